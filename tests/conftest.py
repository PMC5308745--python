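import numpy as np
import pandas as pd
import pytest

from methmark.io import BetaMatrix, ProbeAnnotationTable, SampleDesign
from methmark.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort shared by read-only tests."""
    cfg = SimulationConfig(n_pairs=8, n_probes=3000, n_genes=250, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_design():
    return SampleDesign(pd.DataFrame({
        "sample_id": ["s1T", "s2T", "s3T", "s4T", "s1N", "s2N", "s3N", "s4N"],
        "subject_id": ["s1", "s2", "s3", "s4"] * 2,
        "tissue": ["tumor"] * 4 + ["normal"] * 4,
    }))


def make_beta(values: np.ndarray, probes=None, samples=None, detp=None) -> BetaMatrix:
    values = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i:04d}" for i in range(1, values.shape[0] + 1)]
    samples = samples or [f"S{j}" for j in range(1, values.shape[1] + 1)]
    beta = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"), columns=samples)
    dp = pd.DataFrame(np.zeros_like(values) if detp is None else detp,
                      index=beta.index, columns=samples)
    return BetaMatrix(beta, dp)


def make_annotation(rows: list[dict]) -> ProbeAnnotationTable:
    defaults = {"chromosome": "1", "position": 1000, "gene_symbols": (),
                "region_classes": (), "cgi_class": "OpenSea",
                "snp_flag": False, "multimap_flag": False}
    recs = []
    for r in rows:
        rec = {**defaults, **r}
        recs.append(rec)
    t = pd.DataFrame(recs).set_index("probe_id")
    return ProbeAnnotationTable(t)
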