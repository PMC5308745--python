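"""Synthetic paired tumor/normal cohorts with planted truth, and simulated
MS-HRM melt curves.

The generator emulates the statistical structure a 450K-style paired
screen assumes: per-probe normal-tissue beta drawn from a Beta
distribution whose mean depends on CpG-island context (island promoters
low, open sea high), tumor beta shifted by a planted delta at
differentially methylated probes, hypermethylation enriched in
promoter/CGI context and hypomethylation in non-CGI context, a small
fraction of driver genes carrying >=3 promoter DMPs of one direction
coupled to an opposite-sign expression shift, and a sprinkling of failed
detection p-values. Every output object draws from its own random stream
derived from the master seed by a fixed label, so e.g. adding probes does
not perturb the expression draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .curves import MeltCurve, StandardCurveSet
from .io import BetaMatrix, ExpressionMatrix, ProbeAnnotationTable, SampleDesign

STANDARD_FRACTIONS = (0.0, 0.01, 0.05, 0.10, 0.25, 0.50, 0.75, 0.85, 1.00)

_PROMOTER_REGION_CHOICES = ("TSS200", "TSS1500", "5UTR", "1stExon")
_PROMOTER_REGION_WEIGHTS = (0.3, 0.3, 0.2, 0.2)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the paired-cohort generator.

    Defaults mirror the screening-cohort conditions the pipeline targets:
    six tumor/normal pairs, 43.4% of differential probes hypermethylated,
    5% of genes driver-like (promoter methylation coupled to an opposite
    expression change), hypermethylated DMPs biased 51% promoter / 94.9%
    CGI-related and hypomethylated DMPs 22.2% promoter / 32.7%
    CGI-related.
    """

    n_pairs: int = 6
    n_probes: int = 20_000
    n_genes: int = 1_500
    frac_dmp: float = 0.05
    frac_hyper_among_dmp: float = 0.434
    delta_beta_mean: float = 0.3
    beta_precision: float = 60.0  # concentration of the Beta noise
    frac_driver_genes: float = 0.05
    expr_log2fc_effect: float = 2.0
    expr_noise_sd: float = 0.5
    frac_bad_detection: float = 0.001
    seed: int = 0
    hyper_promoter_frac: float = 0.51
    hyper_cgi_frac: float = 0.949
    hypo_promoter_frac: float = 0.222
    hypo_cgi_frac: float = 0.327

    def __post_init__(self) -> None:
        fracs = {
            "frac_dmp": self.frac_dmp,
            "frac_hyper_among_dmp": self.frac_hyper_among_dmp,
            "frac_driver_genes": self.frac_driver_genes,
            "frac_bad_detection": self.frac_bad_detection,
            "delta_beta_mean": self.delta_beta_mean,
            "hyper_promoter_frac": self.hyper_promoter_frac,
            "hyper_cgi_frac": self.hyper_cgi_frac,
            "hypo_promoter_frac": self.hypo_promoter_frac,
            "hypo_cgi_frac": self.hypo_cgi_frac,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name, v in {"n_pairs": self.n_pairs, "n_probes": self.n_probes,
                        "n_genes": self.n_genes}.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.beta_precision <= 0:
            raise ValueError("beta_precision must be positive")
        if self.expr_noise_sd <= 0:
            raise ValueError("expr_noise_sd must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a simulated cohort, for parameter-recovery checks."""

    dmp_direction: dict[str, str]  # probe -> hyper/hypo
    true_delta: dict[str, float]  # probe -> realized mean tumor-normal shift
    driver_genes: dict[str, tuple[str, str]]  # gene -> (meth_dir, expr_dir)

    def truth_table(self) -> pd.DataFrame:
        rows = [
            {"probe_id": p, "direction": d, "true_delta": self.true_delta[p]}
            for p, d in sorted(self.dmp_direction.items())
        ]
        return pd.DataFrame(rows, columns=["probe_id", "direction", "true_delta"])

    def driver_table(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "meth_direction": m, "expr_direction": e}
            for g, (m, e) in sorted(self.driver_genes.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "meth_direction", "expr_direction"])


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(zlib.crc32(label.encode()),)))
    )


_BASELINE_BY_CGI = {  # normal-tissue mean beta range per CpG context
    "Island": (0.05, 0.25),
    "Shore": (0.15, 0.45),
    "Shelf": (0.40, 0.70),
    "OpenSea": (0.60, 0.90),
}

_CGI_WEIGHTS = {  # probe CpG-context mix by probe location
    "promoter": (0.70, 0.15, 0.05, 0.10),
    "body": (0.15, 0.15, 0.10, 0.60),
    "intergenic": (0.05, 0.10, 0.10, 0.75),
}
_CGI_ORDER = ("Island", "Shore", "Shelf", "OpenSea")


def _build_annotation(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Probe layout: genes get promoter and body probes; the remainder is
    intergenic. All probes are autosomal and QC-clean (the cohort emulates
    a screen after manifest-level probe masking; detection failures are
    planted separately)."""
    genes = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]
    n_prom = 2 + rng.poisson(3.0, size=cfg.n_genes)
    n_body = rng.poisson(3.0, size=cfg.n_genes)

    rows: list[tuple[str, str, str]] = []  # (gene, region, location_kind)
    for g, kp, kb in zip(genes, n_prom, n_body):
        for _ in range(int(kp)):
            region = rng.choice(_PROMOTER_REGION_CHOICES, p=_PROMOTER_REGION_WEIGHTS)
            rows.append((g, str(region), "promoter"))
        for _ in range(int(kb)):
            region = "3UTR" if rng.random() < 0.15 else "Body"
            rows.append((g, str(region), "body"))
        if len(rows) >= cfg.n_probes:
            break
    rows = rows[: cfg.n_probes]
    while len(rows) < cfg.n_probes:
        rows.append(("", "Intergenic", "intergenic"))

    n = len(rows)
    order = rng.permutation(n)
    probe_ids = [f"cg{i:06d}" for i in range(1, n + 1)]
    cgi = np.empty(n, dtype=object)
    for i, k in enumerate(order):
        gene, region, kind = rows[k]
        cgi[i] = rng.choice(_CGI_ORDER, p=_CGI_WEIGHTS[kind])
    table = pd.DataFrame(
        {
            "chromosome": rng.integers(1, 23, size=n).astype(str),
            "position": rng.integers(1, 2_000_000, size=n) * 100 + 1,
            "gene_symbols": [(rows[k][0],) if rows[k][0] else () for k in order],
            "region_classes": [(rows[k][1],) if rows[k][0] else () for k in order],
            "cgi_class": cgi,
            "snp_flag": False,
            "multimap_flag": False,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    table["location_kind"] = [rows[k][2] for k in order]
    return table


def _stratified_pick(
    rng: np.random.Generator,
    pools: dict[tuple[bool, bool], np.ndarray],
    n_total: int,
    p_promoter: float,
    p_cgi: float,
) -> list[int]:
    """Sample probe indices matching independent promoter/CGI marginals."""
    targets = {
        (True, True): p_promoter * p_cgi,
        (True, False): p_promoter * (1 - p_cgi),
        (False, True): (1 - p_promoter) * p_cgi,
        (False, False): (1 - p_promoter) * (1 - p_cgi),
    }
    chosen: list[int] = []
    leftover = 0
    for key in sorted(targets):
        want = int(round(n_total * targets[key]))
        pool = pools[key]
        take = min(want, len(pool))
        leftover += want - take
        if take:
            picked = rng.choice(pool, size=take, replace=False)
            chosen.extend(int(i) for i in picked)
            pools[key] = np.setdiff1d(pool, picked, assume_unique=True)
    # spill any shortfall into whatever remains
    while leftover > 0:
        remaining = np.concatenate([p for p in pools.values() if len(p)])
        if len(remaining) == 0:
            break
        take = min(leftover, len(remaining))
        picked = rng.choice(remaining, size=take, replace=False)
        chosen.extend(int(i) for i in picked)
        for key in pools:
            pools[key] = np.setdiff1d(pools[key], picked, assume_unique=True)
        leftover -= take
    return chosen


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[BetaMatrix, ProbeAnnotationTable, ExpressionMatrix, SampleDesign, PlantedTruth]:
    """Generate one paired cohort with planted differential methylation.

    Driver genes are chosen among genes with >=4 promoter probes and all
    their promoter probes are planted as DMPs of one direction
    (contiguous promoter methylation); their expression shifts by
    ``expr_log2fc_effect`` with the opposite sign. Planted promoter
    hypomethylation starts from a methylated-in-normal baseline so the
    shift has room within [0, 1].
    """
    n_driver = int(round(cfg.frac_driver_genes * cfg.n_genes))
    if n_driver < 1:
        raise ValueError("frac_driver_genes * n_genes must be >= 1")

    ann_table = _build_annotation(cfg, _rng(cfg.seed, "annotation"))
    probe_ids = list(ann_table.index)
    n = len(probe_ids)
    is_promoter = (ann_table["location_kind"] == "promoter").to_numpy()
    is_cgi_related = ann_table["cgi_class"].isin(["Island", "Shore", "Shelf"]).to_numpy()
    gene_of = np.array([g[0] if g else "" for g in ann_table["gene_symbols"]], dtype=object)

    rng_plant = _rng(cfg.seed, "planting")
    # driver genes need a workable promoter block
    prom_counts = pd.Series(gene_of[is_promoter]).value_counts()
    eligible = sorted(prom_counts[prom_counts >= 4].index)
    if len(eligible) < n_driver:
        raise ValueError(
            f"only {len(eligible)} genes have >=4 promoter probes; cannot plant {n_driver} drivers"
        )
    driver_genes = sorted(rng_plant.choice(eligible, size=n_driver, replace=False))

    n_dmp = int(round(cfg.frac_dmp * cfg.n_probes))
    n_hyper_target = int(round(cfg.frac_hyper_among_dmp * n_dmp))
    n_hypo_target = n_dmp - n_hyper_target

    dmp_direction: dict[str, str] = {}
    drivers: dict[str, tuple[str, str]] = {}
    pos_of = {p: i for i, p in enumerate(probe_ids)}
    hyper_used = hypo_used = 0
    for g in driver_genes:
        direction = "hyper" if rng_plant.random() < cfg.frac_hyper_among_dmp else "hypo"
        drivers[g] = (direction, "down" if direction == "hyper" else "up")
        mask = (gene_of == g) & is_promoter
        for i in np.flatnonzero(mask):
            dmp_direction[probe_ids[i]] = direction
        if direction == "hyper":
            hyper_used += int(mask.sum())
        else:
            hypo_used += int(mask.sum())

    taken = np.zeros(n, dtype=bool)
    taken[[pos_of[p] for p in dmp_direction]] = True

    def _pools() -> dict[tuple[bool, bool], np.ndarray]:
        free = ~taken
        return {
            (pr, cg): np.flatnonzero(free & (is_promoter == pr) & (is_cgi_related == cg))
            for pr in (True, False)
            for cg in (True, False)
        }

    for direction, want, p_prom, p_cgi in (
        ("hyper", n_hyper_target - hyper_used, cfg.hyper_promoter_frac, cfg.hyper_cgi_frac),
        ("hypo", n_hypo_target - hypo_used, cfg.hypo_promoter_frac, cfg.hypo_cgi_frac),
    ):
        if want <= 0:
            continue
        picked = _stratified_pick(rng_plant, _pools(), want, p_prom, p_cgi)
        for i in picked:
            dmp_direction[probe_ids[i]] = direction
            taken[i] = True

    # normal-tissue baseline means by CpG context, re-drawn for planted DMPs
    # so the shift fits in [0, 1] (promoter hypomethylation starts from a
    # methylated-in-normal promoter, as observed for real hypo markers)
    rng_beta = _rng(cfg.seed, "beta")
    mu_normal = np.empty(n)
    for cls, (lo, hi) in _BASELINE_BY_CGI.items():
        m = (ann_table["cgi_class"] == cls).to_numpy()
        mu_normal[m] = rng_beta.uniform(lo, hi, size=int(m.sum()))

    direction_arr = np.array([dmp_direction.get(p, "") for p in probe_ids], dtype=object)
    is_hyper = direction_arr == "hyper"
    is_hypo = direction_arr == "hypo"
    mu_normal[is_hyper] = rng_beta.uniform(0.08, 0.45, size=int(is_hyper.sum()))
    mu_normal[is_hypo] = rng_beta.uniform(0.55, 0.90, size=int(is_hypo.sum()))

    delta = np.zeros(n)
    n_planted = int(is_hyper.sum() + is_hypo.sum())
    draws = np.clip(rng_beta.normal(cfg.delta_beta_mean, 0.05, size=n_planted), 0.05, 0.95)
    delta[is_hyper | is_hypo] = draws
    mu_tumor = np.clip(mu_normal + np.where(is_hyper, delta, np.where(is_hypo, -delta, 0.0)),
                       0.02, 0.98)
    mu_normal = np.clip(mu_normal, 0.02, 0.98)
    true_delta = mu_tumor - mu_normal

    phi = cfg.beta_precision
    subjects = [f"P{i:03d}" for i in range(1, cfg.n_pairs + 1)]
    tumor_samples = [f"{s}T" for s in subjects]
    normal_samples = [f"{s}N" for s in subjects]

    def _draw(mu: np.ndarray, k: int) -> np.ndarray:
        a = mu[:, None] * phi
        b = (1.0 - mu)[:, None] * phi
        return np.clip(rng_beta.beta(a, b, size=(n, k)), 0.0, 1.0)

    beta_vals = np.hstack([_draw(mu_tumor, cfg.n_pairs), _draw(mu_normal, cfg.n_pairs)])
    sample_ids = tumor_samples + normal_samples
    beta_df = pd.DataFrame(beta_vals, index=pd.Index(probe_ids, name="probe_id"),
                           columns=sample_ids)

    rng_det = _rng(cfg.seed, "detection")
    detp = rng_det.uniform(0.0, 0.01, size=beta_vals.shape)
    bad = rng_det.random(beta_vals.shape) < cfg.frac_bad_detection
    detp[bad] = rng_det.uniform(0.06, 0.5, size=int(bad.sum()))
    detp_df = pd.DataFrame(detp, index=beta_df.index, columns=sample_ids)

    rng_expr = _rng(cfg.seed, "expression")
    genes = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]
    base = rng_expr.normal(8.0, 1.5, size=cfg.n_genes)
    subj_effect = rng_expr.normal(0.0, 0.3, size=(cfg.n_genes, cfg.n_pairs))
    shift = np.zeros(cfg.n_genes)
    for j, g in enumerate(genes):
        if g in drivers:
            shift[j] = -cfg.expr_log2fc_effect if drivers[g][0] == "hyper" else cfg.expr_log2fc_effect
    log2_tumor = (base[:, None] + subj_effect + shift[:, None]
                  + rng_expr.normal(0.0, cfg.expr_noise_sd, size=(cfg.n_genes, cfg.n_pairs)))
    log2_normal = (base[:, None] + subj_effect
                   + rng_expr.normal(0.0, cfg.expr_noise_sd, size=(cfg.n_genes, cfg.n_pairs)))
    intensity = np.hstack([2.0 ** log2_tumor, 2.0 ** log2_normal])
    feature_ids = [f"EP{i:05d}" for i in range(1, cfg.n_genes + 1)]
    expr = ExpressionMatrix(
        pd.DataFrame(intensity, index=pd.Index(feature_ids, name="feature_id"),
                     columns=sample_ids),
        pd.Series(genes, index=pd.Index(feature_ids, name="feature_id"), name="gene_symbol"),
    )

    design = SampleDesign(pd.DataFrame({
        "sample_id": sample_ids,
        "subject_id": subjects + subjects,
        "tissue": ["tumor"] * cfg.n_pairs + ["normal"] * cfg.n_pairs,
    }))

    truth = PlantedTruth(
        dmp_direction=dmp_direction,
        true_delta={p: float(true_delta[pos_of[p]]) for p in dmp_direction},
        driver_genes=drivers,
    )
    ann = ProbeAnnotationTable(ann_table.drop(columns=["location_kind"]))
    return BetaMatrix(beta_df, detp_df), ann, expr, design, truth


# --- MS-HRM melt-curve simulation -------------------------------------------

TM_UNMETH = 78.0  # deg C
TM_METH = 82.0
LOGISTIC_SLOPE = 1.5  # per deg C
TEMP_GRID = (70.0, 90.0, 0.1)


def _logistic_melt(temp: np.ndarray, tm: float, slope: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(slope * (temp - tm)))


def simulate_melt_curves(
    methylation_fractions: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    tm_meth: float = TM_METH,
    tm_unmeth: float = TM_UNMETH,
    slope: float = LOGISTIC_SLOPE,
) -> list[MeltCurve]:
    """Melt curves of methylated/unmethylated template mixtures.

    Each curve is F(T) = m*S(T; Tm_meth) + (1-m)*S(T; Tm_unmeth) + noise
    with S a decreasing logistic and Tm_meth > Tm_unmeth, then
    renormalized so F(start)=1 and F(end)=0.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if tm_meth <= tm_unmeth:
        raise ValueError("methylated template must melt higher than unmethylated")
    for m in methylation_fractions:
        if not 0.0 <= m <= 1.0:
            raise ValueError(f"methylation fraction {m} outside [0, 1]")
    lo, hi, step = TEMP_GRID
    temp = np.arange(lo, hi + step / 2, step)
    s_meth = _logistic_melt(temp, tm_meth, slope)
    s_unmeth = _logistic_melt(temp, tm_unmeth, slope)
    rng = _rng(seed, "melt")
    out = []
    for m in methylation_fractions:
        f = m * s_meth + (1.0 - m) * s_unmeth
        if noise_sd > 0:
            f = f + rng.normal(0.0, noise_sd, size=f.shape)
        out.append(MeltCurve(temp, f, label=f"m={m:g}").normalized())
    return out


def simulate_standard_curves(
    fractions: tuple[float, ...] = STANDARD_FRACTIONS,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> StandardCurveSet:
    """The standard dilution series (0, 1, 5, 10, 25, 50, 75, 85, 100%)."""
    curves = simulate_melt_curves(list(fractions), noise_sd=noise_sd, seed=seed)
    return StandardCurveSet(list(zip(fractions, curves)))
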