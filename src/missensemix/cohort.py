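"""Case-control cohort data model and TSV input/output.

A cohort couples a variant catalog (one row per variant, with consequence
class, allele frequency, in silico scores, protein-domain label and optional
functional/clinical classifications) to a subject table (one row per person,
with country/ethnicity stratum, case-control status, age, study design and
the set of carried variant ids).  All downstream analyses consume this pair.

Files are plain UTF-8 TSV with a mandatory header; missing values are the
literal token ``NA``; the ``carried`` column is a semicolon-separated list of
variant ids (empty allowed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IntegrityError, ParseError

VARIANT_COLUMNS = [
    "gene", "variant_id", "consequence", "frequency",
    "cadd", "helix", "bayesdel", "revel", "align_gvgd",
    "domain", "splice_excluded", "sge_class", "hdr_class", "clinvar_class",
]
SCORE_COLUMNS = ["cadd", "helix", "bayesdel", "revel", "align_gvgd"]
SUBJECT_COLUMNS = ["subject_id", "stratum", "status", "age", "design", "carried"]

NA_TOKEN = "NA"


@dataclass
class Cohort:
    """Subjects plus the variant catalog they refer to.

    ``variants`` and ``subjects`` are pandas DataFrames with the canonical
    columns above; ``subjects.carried`` holds tuples of variant ids.
    ``removal_log`` accumulates counts of subjects removed per reason by
    :func:`filter_subjects`.
    """

    variants: pd.DataFrame
    subjects: pd.DataFrame
    removal_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- integrity ---------------------------------------------------------
    def validate(self) -> None:
        v, s = self.variants, self.subjects
        dup = v["variant_id"][v["variant_id"].duplicated()]
        if len(dup):
            raise IntegrityError(f"duplicate variant_id(s): {sorted(set(dup))[:5]}")
        dup = s["subject_id"][s["subject_id"].duplicated()]
        if len(dup):
            raise IntegrityError(f"duplicate subject_id(s): {sorted(set(dup))[:5]}")
        bad = v["frequency"][(v["frequency"] < 0) | (v["frequency"] > 1)]
        if len(bad):
            raise IntegrityError(f"allele frequency outside [0,1] for {bad.index.tolist()[:5]}")
        bad_status = set(s["status"]) - {"case", "control"}
        if bad_status:
            raise IntegrityError(f"invalid status value(s): {sorted(bad_status)}")
        if (s["stratum"].astype(str).str.len() == 0).any():
            raise IntegrityError("empty stratum label")
        known = set(v["variant_id"])
        for sid, carried in zip(s["subject_id"], s["carried"]):
            missing = [c for c in carried if c not in known]
            if missing:
                raise IntegrityError(
                    f"subject {sid!r} references unknown variant id(s) {missing[:3]}"
                )

    # -- convenience views -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def carriage(self) -> pd.DataFrame:
        """Long (subject_id, variant_id) carriage table."""
        s = self.subjects
        rows = s.loc[s["carried"].map(len) > 0, ["subject_id", "carried"]]
        long = rows.explode("carried").rename(columns={"carried": "variant_id"})
        return long.reset_index(drop=True)

    def subset_subjects(self, subject_ids) -> "Cohort":
        keep = self.subjects["subject_id"].isin(set(subject_ids))
        return Cohort(self.variants, self.subjects.loc[keep].reset_index(drop=True))

    def variant(self, variant_id: str) -> pd.Series:
        hit = self.variants.loc[self.variants["variant_id"] == variant_id]
        if hit.empty:
            raise IntegrityError(f"unknown variant id {variant_id!r}")
        return hit.iloc[0]


# ---------------------------------------------------------------------------
# reading and writing
# ---------------------------------------------------------------------------

def _numeric(series: pd.Series, column: str, path) -> pd.Series:
    raw = series.replace(NA_TOKEN, np.nan)
    out = pd.to_numeric(raw, errors="coerce")
    bad = raw.notna() & out.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise ParseError(f"{path}: unparseable numeric {column!r} at line {line}")
    return out


def _boolean(series: pd.Series, column: str, path) -> pd.Series:
    low = series.astype(str).str.lower()
    ok = low.isin(["true", "false"])
    if not ok.all():
        line = int((~ok).idxmax()) + 2
        raise ParseError(f"{path}: unparseable boolean {column!r} at line {line}")
    return low == "true"


def read_variants(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    df["frequency"] = _numeric(df["frequency"], "frequency", path)
    for col in SCORE_COLUMNS:
        df[col] = _numeric(df[col], col, path)
    df["splice_excluded"] = _boolean(df["splice_excluded"], "splice_excluded", path)
    for col in ("sge_class", "hdr_class", "clinvar_class", "domain"):
        df[col] = df[col].replace("", NA_TOKEN)
    return df[VARIANT_COLUMNS]


def read_subjects(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    df["age"] = _numeric(df["age"], "age", path)
    df["carried"] = [
        tuple(x for x in carried.split(";") if x) for carried in df["carried"]
    ]
    return df[SUBJECT_COLUMNS]


def read_cohort(variants_path, subjects_path) -> Cohort:
    """Load a cohort from its two TSV files and verify referential integrity."""
    return Cohort(read_variants(variants_path), read_subjects(subjects_path))


def _format_value(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return NA_TOKEN
    if isinstance(x, (bool, np.bool_)):
        return "true" if x else "false"
    if isinstance(x, float):
        return repr(x)  # shortest round-trippable representation
    return str(x)


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write variants.tsv and subjects.tsv under ``out_dir``; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vpath, spath = out_dir / "variants.tsv", out_dir / "subjects.tsv"

    v = cohort.variants.copy()
    for col in v.columns:
        v[col] = v[col].map(_format_value)
    v.to_csv(vpath, sep="\t", index=False)

    s = cohort.subjects.copy()
    s["carried"] = s["carried"].map(";".join)
    for col in s.columns:
        s[col] = s[col].map(_format_value)
    s.to_csv(spath, sep="\t", index=False)
    return {"variants": str(vpath), "subjects": str(spath)}


def write_report(tables: dict, out_dir) -> dict:
    """Write one TSV per named result table; return a manifest.

    The manifest maps table name to ``{"path": ..., "rows": ...}`` and is also
    written as ``manifest.json`` in ``out_dir``.  Numeric cells use full float
    precision so a re-read reproduces the values exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN,
                     float_format=lambda x: repr(float(x)))
        manifest[name] = {"path": str(path), "rows": int(len(table))}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# cohort partitioning and filtering
# ---------------------------------------------------------------------------

def split_train_validation(cohort: Cohort, fraction: float, eligible_strata,
                           seed: int) -> tuple[Cohort, Cohort]:
    """Stratified training/validation split.

    The validation set is drawn only from population-design subjects in
    ``eligible_strata``; sampling is stratified by (stratum, status) so the
    validation case:control mix per stratum tracks the eligible pool.  All
    remaining subjects (including every familial-design subject) stay in
    training.  Deterministic for a fixed ``seed``.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0,1), got {fraction}")
    s = cohort.subjects
    eligible = (s["design"] == "population") & s["stratum"].isin(set(eligible_strata))
    if not eligible.any():
        raise ValueError("no eligible subjects for the validation split")

    rng = np.random.default_rng(seed)
    val_idx: list[np.ndarray] = []
    pool = s.loc[eligible]
    for _, grp in pool.groupby(["stratum", "status"], sort=True):
        k = int(round(fraction * len(grp)))
        if k:
            val_idx.append(rng.choice(grp.index.to_numpy(), size=k, replace=False))
    chosen = np.concatenate(val_idx) if val_idx else np.array([], dtype=int)
    mask = s.index.isin(chosen)
    validation = Cohort(cohort.variants, s.loc[mask].reset_index(drop=True))
    training = Cohort(cohort.variants, s.loc[~mask].reset_index(drop=True))
    return training, validation


def filter_subjects(cohort: Cohort, drop_ptv_carriers_in=(),
                    drop_multi_missense_genes: bool = False) -> Cohort:
    """Remove flagged subjects; the removal log travels with the result.

    ``drop_ptv_carriers_in``: subjects carrying a PTV in any listed gene are
    removed (the standard exclusion for all analyses except the mixture fits).
    ``drop_multi_missense_genes``: subjects carrying two or more missense
    variants of the same gene are removed.
    """
    v = cohort.variants
    ptv_ids = set(v.loc[(v["consequence"] == "PTV")
                        & v["gene"].isin(set(drop_ptv_carriers_in)), "variant_id"])
    mis_gene = dict(zip(v.loc[v["consequence"] == "missense", "variant_id"],
                        v.loc[v["consequence"] == "missense", "gene"]))

    drop_ptv = np.zeros(len(cohort.subjects), dtype=bool)
    drop_multi = np.zeros(len(cohort.subjects), dtype=bool)
    for i, carried in enumerate(cohort.subjects["carried"]):
        if ptv_ids and any(c in ptv_ids for c in carried):
            drop_ptv[i] = True
        if drop_multi_missense_genes:
            genes = [mis_gene[c] for c in carried if c in mis_gene]
            if len(genes) != len(set(genes)):
                drop_multi[i] = True

    keep = ~(drop_ptv | drop_multi)
    out = Cohort(cohort.variants, cohort.subjects.loc[keep].reset_index(drop=True))
    out.removal_log = dict(cohort.removal_log)
    out.removal_log["ptv_carrier"] = int(drop_ptv.sum())
    out.removal_log["multi_missense_same_gene"] = int((drop_multi & ~drop_ptv).sum())
    return out
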