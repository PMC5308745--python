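"""Domain types and tab-delimited readers/writers.

All tabular inputs follow GEO series-matrix conventions: tab-delimited
UTF-8, probes/features in rows, samples in columns, ``NA`` for missing.
Beta values are methylation fractions in [0, 1]; detection p-values share
the beta matrix shape. Genomic coordinates are 1-based inclusive; strand
is ignored (beta is strand-symmetric after bisulfite summarization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PROMOTER_REGIONS = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon"})
REGION_CLASSES = ("TSS200", "TSS1500", "5UTR", "1stExon", "Body", "3UTR", "Intergenic")
CGI_CLASSES = ("Island", "Shore", "Shelf", "OpenSea")
CGI_RELATED = frozenset({"Island", "Shore", "Shelf"})

NA_REP = "NA"


class ParseError(ValueError):
    """Malformed or invariant-violating input file."""


@dataclass(frozen=True)
class SampleDesign:
    """Paired tumor/normal sample sheet.

    Each subject contributes at most one tumor and one normal sample;
    subjects with both form the paired set used by every paired test.
    """

    table: pd.DataFrame  # columns: sample_id, subject_id, tissue

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample_id", "subject_id", "tissue"}
        if not required.issubset(t.columns):
            raise ParseError(f"design table needs columns {sorted(required)}")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ParseError(f"duplicate sample_id {dup!r} in design")
        bad = set(t["tissue"]) - {"tumor", "normal"}
        if bad:
            raise ParseError(f"tissue must be tumor/normal, got {sorted(bad)}")
        if t.duplicated(subset=["subject_id", "tissue"]).any():
            raise ParseError("a subject appears more than once per tissue")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def pairs(self) -> list[tuple[str, str]]:
        """(tumor_sample, normal_sample) per paired subject, sorted by subject."""
        wide = self.table.pivot(index="subject_id", columns="tissue", values="sample_id")
        if "tumor" not in wide.columns or "normal" not in wide.columns:
            return []
        paired = wide.dropna(subset=["tumor", "normal"]).sort_index()
        return list(zip(paired["tumor"], paired["normal"]))


def _check_unit_interval(df: pd.DataFrame, what: str) -> None:
    vals = df.to_numpy(dtype=float)
    bad = (vals < 0) | (vals > 1)
    if np.any(bad & ~np.isnan(vals)):
        i, j = np.argwhere(bad & ~np.isnan(vals))[0]
        raise ParseError(
            f"{what}={vals[i, j]} out of [0,1] at probe {df.index[i]!r}, sample {df.columns[j]!r}"
        )


@dataclass(frozen=True)
class BetaMatrix:
    """Probes x samples methylation fractions plus detection p-values."""

    beta: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        if self.beta.index.duplicated().any():
            dup = self.beta.index[self.beta.index.duplicated()][0]
            raise ParseError(f"duplicate probe id {dup!r}")
        if self.beta.shape != self.detection_p.shape:
            raise ParseError(
                f"beta {self.beta.shape} and detection_p {self.detection_p.shape} differ in shape"
            )
        _check_unit_interval(self.beta, "beta")
        _check_unit_interval(self.detection_p, "detection p")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    def subset_probes(self, probes: Iterable[str]) -> "BetaMatrix":
        idx = [p for p in self.beta.index if p in set(probes)]
        return BetaMatrix(self.beta.loc[idx], self.detection_p.loc[idx])


@dataclass(frozen=True)
class ProbeAnnotationTable:
    """Per-probe genomic context: position, gene/region assignments, CGI class, QC flags.

    ``gene_symbols`` and ``region_classes`` are parallel tuples: a probe
    annotated to several genes carries one region class per gene (450K
    manifest semantics).
    """

    table: pd.DataFrame  # index probe_id; columns chromosome, position,
    # gene_symbols (tuple), region_classes (tuple), cgi_class, snp_flag, multimap_flag

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise ParseError("duplicate probe id in annotation")
        bad_cgi = set(t["cgi_class"]) - set(CGI_CLASSES)
        if bad_cgi:
            raise ParseError(f"unknown cgi_class values {sorted(bad_cgi)}")
        for pid, genes, regions in zip(t.index, t["gene_symbols"], t["region_classes"]):
            if len(genes) != len(regions):
                raise ParseError(f"probe {pid!r}: gene/region lists differ in length")
            if genes and not regions:
                raise ParseError(f"probe {pid!r}: genes without region classes")
            unknown = set(regions) - set(REGION_CLASSES)
            if unknown:
                raise ParseError(f"probe {pid!r}: unknown region classes {sorted(unknown)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def subset(self, probes: Iterable[str]) -> "ProbeAnnotationTable":
        keep = set(probes)
        return ProbeAnnotationTable(self.table.loc[[p for p in self.table.index if p in keep]])


@dataclass(frozen=True)
class ExpressionMatrix:
    """Expression features x samples, nonnegative intensities, feature->gene map."""

    intensity: pd.DataFrame
    gene_symbols: pd.Series  # index: feature ids, values: gene symbol ("" if unknown)
    n_missing_symbols: int = 0

    def __post_init__(self) -> None:
        if self.intensity.index.duplicated().any():
            dup = self.intensity.index[self.intensity.index.duplicated()][0]
            raise ParseError(f"duplicate feature id {dup!r}")
        vals = self.intensity.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            i, j = np.argwhere(np.nan_to_num(vals, nan=0.0) < 0)[0]
            raise ParseError(
                f"negative intensity at feature {self.intensity.index[i]!r}, "
                f"sample {self.intensity.columns[j]!r}"
            )
        if not self.gene_symbols.index.equals(self.intensity.index):
            raise ParseError("gene_symbols index must match intensity features")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensity.columns)


def read_design(path: str | Path) -> SampleDesign:
    t = pd.read_csv(path, sep="\t", dtype=str)
    return SampleDesign(t)


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def _read_numeric_matrix(path: str | Path, what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_REP])
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ParseError(f"cannot parse {what} file {path}: {exc}") from exc
    if df.columns.empty:
        raise ParseError(f"{what} file {path} has no sample columns (malformed header?)")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise ParseError(
                    f"non-numeric {what} at probe {bad[0]!r}, sample {col!r} in {path}"
                )
            df[col] = coerced
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def _split_multi(value: object) -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return ()
    return tuple(str(value).split(";"))


def read_annotation(path: str | Path) -> ProbeAnnotationTable:
    raw = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA_REP])
    required = {"probe_id", "chromosome", "position", "gene_symbols", "region_classes",
                "cgi_class", "snp_flag", "multimap_flag"}
    missing = required - set(raw.columns)
    if missing:
        raise ParseError(f"annotation missing columns {sorted(missing)}")
    flag_map = {"True": True, "False": False, "1": True, "0": False}
    t = pd.DataFrame(
        {
            "chromosome": raw["chromosome"].fillna("").to_numpy(),
            "position": pd.to_numeric(raw["position"], errors="raise").astype(int).to_numpy(),
            "gene_symbols": raw["gene_symbols"].map(_split_multi).to_numpy(),
            "region_classes": raw["region_classes"].map(_split_multi).to_numpy(),
            "cgi_class": raw["cgi_class"].to_numpy(),
            "snp_flag": raw["snp_flag"].map(flag_map).to_numpy(),
            "multimap_flag": raw["multimap_flag"].map(flag_map).to_numpy(),
        },
        index=pd.Index(raw["probe_id"].astype(str), name="probe_id"),
    )
    return ProbeAnnotationTable(t)


def write_annotation(ann: ProbeAnnotationTable, path: str | Path) -> None:
    t = ann.table
    out = pd.DataFrame(
        {
            "probe_id": t.index,
            "chromosome": t["chromosome"].values,
            "position": t["position"].values,
            "gene_symbols": [";".join(g) for g in t["gene_symbols"]],
            "region_classes": [";".join(r) for r in t["region_classes"]],
            "cgi_class": t["cgi_class"].values,
            "snp_flag": t["snp_flag"].values,
            "multimap_flag": t["multimap_flag"].values,
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_beta_matrix(
    path: str | Path,
    annotation_path: str | Path,
    detection_p_path: str | Path | None = None,
) -> tuple[BetaMatrix, ProbeAnnotationTable, list[str]]:
    """Read a beta matrix plus its probe annotation.

    Probes present in the beta matrix but absent from the annotation are
    dropped; their ids are returned as the third element and reported via
    a warning. When no detection-p file is given, all detection p-values
    are taken to be 0 (every probe reliably detected).
    """
    beta = _read_numeric_matrix(path, "beta")
    if detection_p_path is not None:
        detp = _read_numeric_matrix(detection_p_path, "detection p")
        if not detp.index.equals(beta.index) or not detp.columns.equals(beta.columns):
            raise ParseError("detection-p matrix rows/columns do not match beta matrix")
    else:
        detp = pd.DataFrame(0.0, index=beta.index, columns=beta.columns)
    ann = read_annotation(annotation_path)
    known = set(ann.probe_ids)
    dropped = [p for p in beta.index if p not in known]
    if dropped:
        warnings.warn(
            f"{len(dropped)} probes absent from annotation were dropped "
            f"(first: {dropped[0]!r})",
            stacklevel=2,
        )
        keep = [p for p in beta.index if p in known]
        beta = beta.loc[keep]
        detp = detp.loc[keep]
    bm = BetaMatrix(beta, detp)
    return bm, ann.subset(bm.probe_ids), dropped


def write_beta_matrix(bm: BetaMatrix, beta_path: str | Path, detp_path: str | Path | None = None) -> None:
    bm.beta.to_csv(beta_path, sep="\t", na_rep=NA_REP, index_label="probe_id")
    if detp_path is not None:
        bm.detection_p.to_csv(detp_path, sep="\t", na_rep=NA_REP, index_label="probe_id")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a feature-by-sample expression matrix.

    First column is the feature id, second the gene symbol; remaining
    columns are samples. Features with a missing symbol are retained with
    an empty symbol and counted in ``n_missing_symbols``.
    """
    raw = pd.read_csv(path, sep="\t", na_values=[NA_REP])
    if raw.shape[1] < 3:
        raise ParseError(f"expression file {path} needs feature, gene and >=1 sample column")
    feat_col, gene_col = raw.columns[0], raw.columns[1]
    features = raw[feat_col].astype(str)
    if features.duplicated().any():
        raise ParseError(f"duplicate feature id {features[features.duplicated()].iloc[0]!r}")
    symbols = raw[gene_col].fillna("").astype(str)
    n_missing = int((symbols == "").sum())
    if n_missing:
        warnings.warn(f"{n_missing} features lack a gene symbol", stacklevel=2)
    intensity = raw.drop(columns=[feat_col, gene_col]).astype(float)
    intensity.index = pd.Index(features, name="feature_id")
    return ExpressionMatrix(
        intensity, pd.Series(symbols.values, index=intensity.index, name="gene_symbol"),
        n_missing_symbols=n_missing,
    )


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.intensity.copy()
    out.insert(0, "gene_symbol", expr.gene_symbols)
    out.to_csv(path, sep="\t", na_rep=NA_REP, index_label="feature_id")


def write_results_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a results table deterministically.

    Rows sorted by key, column order as given, floats rendered with six
    significant digits, so two writes of the same table are byte-identical.
    """
    out = table.sort_index()
    out.to_csv(path, sep="\t", na_rep=NA_REP, float_format="%.6g",
               index_label=out.index.name or "key")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_REP])
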