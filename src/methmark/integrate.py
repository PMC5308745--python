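"""Promoter-proxy aggregation and inverse methylation-expression marker selection.

A gene's methylation level is proxied by the unweighted mean beta of its
*differentially methylated* promoter CpGs (TSS1500, TSS200, 5'UTR, 1st
exon) — not of all promoter probes — since transcriptional silencing does
not require aberrant methylation of the whole promoter. Candidate markers
are genes whose proxy methylation direction is opposite to their
expression call (hyper & down, or hypo & up); the reported panel keeps
candidates with strictly more than ``min_probes_exclusive`` differential
promoter CpGs.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .io import PROMOTER_REGIONS, ProbeAnnotationTable

TABLE_COLUMNS = ["probe_number", "mean_beta_normal", "mean_beta_cancer", "delta_beta"]


def promoter_proxy(dmps: pd.DataFrame, ann: ProbeAnnotationTable) -> pd.DataFrame:
    """Aggregate called DMPs in promoter regions to per-gene proxies.

    For each gene, collect the called DMPs whose region class *for that
    gene* is a promoter class; a probe annotated to several genes
    contributes to each under its own region class, and duplicate
    probe-gene assignments count once. Genes with no such probe are
    absent. Returns a frame indexed by gene with probe_count, group mean
    betas, delta_beta (cancer - normal), meth_direction and a
    mixed_direction flag (contributing DMPs of both signs).
    """
    called = dmps[dmps["direction"].isin(["hyper", "hypo"])]
    contributions: dict[str, set[str]] = {}
    for probe in called.index:
        if probe not in ann.table.index:
            continue
        row = ann.table.loc[probe]
        for gene, region in zip(row["gene_symbols"], row["region_classes"]):
            if region in PROMOTER_REGIONS and gene:
                contributions.setdefault(gene, set()).add(probe)

    records = []
    for gene in sorted(contributions):
        probes = sorted(contributions[gene])
        sub = called.loc[probes]
        mean_n = float(sub["mean_beta_normal"].mean())
        mean_c = float(sub["mean_beta_cancer"].mean())
        delta = mean_c - mean_n
        directions = set(sub["direction"])
        records.append(
            {
                "gene": gene,
                "probe_count": len(probes),
                "mean_beta_normal": mean_n,
                "mean_beta_cancer": mean_c,
                "delta_beta": delta,
                "meth_direction": "hyper" if delta > 0 else "hypo",
                "mixed_direction": len(directions) > 1,
            }
        )
    if not records:
        return pd.DataFrame(
            columns=["probe_count", "mean_beta_normal", "mean_beta_cancer",
                     "delta_beta", "meth_direction", "mixed_direction"],
        ).rename_axis("gene")
    return pd.DataFrame.from_records(records).set_index("gene")


def classify_inverse(proxies: pd.DataFrame, degs: pd.DataFrame) -> pd.DataFrame:
    """Flag genes whose methylation and expression changes are inverse.

    inverse is true iff (hyper & expression down) or (hypo & expression
    up); genes without a differential-expression call stay inverse=false.
    ``result.attrs['inverse_fraction']`` reports the fraction of
    aberrantly methylated genes (all proxy genes) that are inverse.
    """
    out = proxies.copy()
    expr_dir = degs["direction"] if "direction" in degs else pd.Series(dtype=object)
    out["expr_direction"] = [expr_dir.get(g, "none") for g in out.index]
    out["inverse"] = (
        ((out["meth_direction"] == "hyper") & (out["expr_direction"] == "down"))
        | ((out["meth_direction"] == "hypo") & (out["expr_direction"] == "up"))
    )
    out.attrs["inverse_fraction"] = float(out["inverse"].mean()) if len(out) else float("nan")
    return out


def select_markers(candidates: pd.DataFrame, min_probes_exclusive: int = 2) -> pd.DataFrame:
    """Select the marker panel: inverse AND probe_count strictly greater
    than ``min_probes_exclusive``.

    Returns the selected genes sorted by probe count descending then gene
    name, with the published table layout (probe_number, mean beta in
    normal and cancer, delta beta).
    """
    sel = candidates[candidates["inverse"] & (candidates["probe_count"] > min_probes_exclusive)]
    # probe_count descending, gene name ascending as the tie-break
    sel = sel.sort_index(kind="stable").sort_values("probe_count", ascending=False, kind="stable")
    out = sel.rename(columns={"probe_count": "probe_number"})[
        ["probe_number", "mean_beta_normal", "mean_beta_cancer", "delta_beta"]
    ]
    out.attrs["n_candidates"] = int(len(candidates))
    return out


def load_table1_fixture() -> pd.DataFrame:
    """Load the packaged 36-gene candidate table.

    Directions are derived at load time: meth_direction from the sign of
    the printed delta beta, expr_direction as its opposite (every listed
    gene had an inverse expression change), inverse therefore true.
    """
    path = files("methmark.data").joinpath("table1_fixture.tsv")
    with path.open("r", encoding="utf-8") as fh:
        t = pd.read_csv(fh, sep="\t").set_index("gene")
    t["meth_direction"] = ["hyper" if d > 0 else "hypo" for d in t["delta_beta"]]
    t["expr_direction"] = ["down" if d == "hyper" else "up" for d in t["meth_direction"]]
    t["inverse"] = True
    return t


def replay_table1(min_probes_exclusive: int = 2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-derive delta beta and the marker selection from the packaged table.

    Returns (fixture with recomputed delta, selected panel). The
    recomputed delta beta (mean cancer - mean normal) is what downstream
    checks compare against the printed column.
    """
    fixture = load_table1_fixture()
    candidates = fixture.rename(columns={"probe_number": "probe_count"}).copy()
    candidates["printed_delta_beta"] = candidates["delta_beta"]
    candidates["delta_beta"] = candidates["mean_beta_cancer"] - candidates["mean_beta_normal"]
    selected = select_markers(candidates, min_probes_exclusive=min_probes_exclusive)
    return candidates, selected
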