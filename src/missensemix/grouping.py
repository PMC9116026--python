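"""Variant eligibility filters and risk-category schemes.

A risk-category scheme partitions the eligible rare missense variants of one
gene into ordered categories using protein-domain membership, in silico score
cuts and (for the layered schemes) functional-assay classes.  Schemes are
declarative and YAML-serialisable: each category carries a predicate built
from a small condition language, and predicates must partition the eligible
set -- a variant matching zero or two categories is a hard error, never a
silent drop.

Built-in schemes reproduce the published per-gene category definitions:

* ATM      -- outside FAT/PIK; inside & CADD quintiles 1-4; inside & CADD Q5
              (fixed published boundary 3.736542 by default)
* BRCA1    -- outside RING/BRCT; inside & Helix-low; inside & Helix-high
* BRCA2    -- Helix-low; Helix-high
* CHEK2    -- Helix-low; Helix-high
* PALB2    -- a single all-carriers category
* BRCA1-SGE  (layered) -- INT/LOF by saturation genome editing; then the
              domain+Helix split for unassayed variants; FUNC or outside-domain
* BRCA2-HDR  (layered) -- LP/P by the homology-directed-repair assay; then the
              Helix split for unassayed variants; LB/B
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort
from .errors import PartitionError

RARE_THRESHOLD = 0.001      # "rare" means allele frequency strictly below 0.1%
HELIX_CUT = 0.5
ATM_CADD_Q5_BOUNDARY = 3.736542   # published empirical quintile boundary

FREQUENCY_BIN_LABELS = ["<0.1%", "0.1–0.5%", "0.5–1%", "1–5%"]
FREQUENCY_BIN_EDGES = [0.0, 0.001, 0.005, 0.01, 0.05]


# ---------------------------------------------------------------------------
# elementary classifiers
# ---------------------------------------------------------------------------

def eligible_missense(catalog: pd.DataFrame, gene: str,
                      rare_threshold: float = RARE_THRESHOLD) -> set[str]:
    """Rare (< threshold), non-splice-flagged missense variants of ``gene``."""
    if not 0 < rare_threshold <= 0.05:
        raise ValueError(f"rare_threshold must be in (0, 0.05], got {rare_threshold}")
    if gene not in set(catalog["gene"]):
        raise ValueError(f"unknown gene {gene!r}")
    keep = ((catalog["gene"] == gene)
            & (catalog["consequence"] == "missense")
            & (catalog["frequency"] < rare_threshold)
            & ~catalog["splice_excluded"])
    return set(catalog.loc[keep, "variant_id"])


def classify_frequency(frequency: float, bins=None) -> str:
    """Assign an allele frequency to one of the four reporting bins.

    Intervals are left-closed/right-open; anything above 5% is out of range.
    """
    edges = FREQUENCY_BIN_EDGES if bins is None else list(bins)
    labels = FREQUENCY_BIN_LABELS if bins is None else None
    if frequency < 0 or frequency > edges[-1]:
        raise ValueError(f"frequency {frequency} outside [0, {edges[-1]}]")
    idx = int(np.searchsorted(edges, frequency, side="right")) - 1
    idx = min(idx, len(edges) - 2)
    return labels[idx] if labels else idx


def quantile_boundaries(values, k: int) -> np.ndarray:
    """k-1 empirical quantile cut points (type-7 linear interpolation)."""
    arr = np.asarray(list(values), dtype=float)
    if len(np.unique(arr)) < k:
        raise ValueError(f"need at least {k} distinct values, got {len(np.unique(arr))}")
    qs = np.arange(1, k) / k
    return np.quantile(arr, qs, method="linear")


def helix_class(score: float) -> str:
    """Dichotomise a Helix score: 'high' (deleterious) iff score > 0.5.

    A score of exactly 0.5 is assigned to 'low' (the conservative choice for a
    boundary the published definition leaves open).  A missing score is an
    error: such a variant cannot enter a Helix-based scheme.
    """
    if score is None or (isinstance(score, float) and np.isnan(score)):
        raise ValueError("missing Helix score")
    return "high" if score > HELIX_CUT else "low"


# ---------------------------------------------------------------------------
# predicates
# ---------------------------------------------------------------------------

def _eval_condition(cond: dict, row: pd.Series) -> bool:
    """Evaluate one predicate dict against a variant record (AND semantics).

    Supported keys:
      match_all: true               -- tautology (catch-all categories)
      any: [cond, ...]              -- OR over sub-conditions
      domain_in / domain_not_in     -- protein-domain membership
      class_in: {field:, values:}   -- categorical field, "NA" means missing
      score_gt / score_le: {score:, value:}  -- numeric cut; NaN never matches
    """
    for key, spec in cond.items():
        if key == "match_all":
            continue
        if key == "any":
            if not any(_eval_condition(c, row) for c in spec):
                return False
        elif key == "domain_in":
            if row["domain"] not in set(spec):
                return False
        elif key == "domain_not_in":
            if row["domain"] in set(spec):
                return False
        elif key == "class_in":
            if row[spec["field"]] not in set(spec["values"]):
                return False
        elif key in ("score_gt", "score_le"):
            val = row[spec["score"]]
            if val is None or (isinstance(val, float) and np.isnan(val)):
                return False
            if key == "score_gt" and not val > spec["value"]:
                return False
            if key == "score_le" and not val <= spec["value"]:
                return False
        else:
            raise ValueError(f"unknown predicate key {key!r}")
    return True


@dataclass
class RiskGroupScheme:
    """Ordered risk categories for one gene, with their defining predicates."""

    gene: str
    categories: list  # list of (label, predicate-dict)
    baseline_label: str
    params: dict = field(default_factory=dict)
    rare_threshold: float = RARE_THRESHOLD

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.categories]

    def to_yaml(self, path=None) -> str:
        doc = {
            "gene": self.gene,
            "baseline": self.baseline_label,
            "rare_threshold": self.rare_threshold,
            "params": self.params,
            "categories": [{"label": lab, "when": cond} for lab, cond in self.categories],
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RiskGroupScheme":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        else:
            text = str(source)
            if "\n" not in text and text.endswith((".yaml", ".yml")):
                with open(text) as fh:
                    doc = yaml.safe_load(fh)
            else:
                doc = yaml.safe_load(text)
        return cls(
            gene=doc["gene"],
            categories=[(c["label"], c["when"]) for c in doc["categories"]],
            baseline_label=doc["baseline"],
            params=doc.get("params", {}),
            rare_threshold=doc.get("rare_threshold", RARE_THRESHOLD),
        )


@dataclass
class GroupAssignment:
    """The realised variant -> category map for one gene under one scheme."""

    gene: str
    mapping: dict  # variant_id -> category label
    scheme: RiskGroupScheme

    @property
    def labels(self) -> list[str]:
        return self.scheme.labels

    def variants_in(self, label: str) -> list[str]:
        return [v for v, lab in self.mapping.items() if lab == label]

    def counts(self) -> pd.Series:
        out = pd.Series(0, index=self.labels, dtype=int)
        for lab in self.mapping.values():
            out[lab] += 1
        return out


def assign_groups(catalog: pd.DataFrame, scheme: RiskGroupScheme) -> GroupAssignment:
    """Partition the eligible variants of the scheme's gene into categories."""
    eligible = eligible_missense(catalog, scheme.gene, scheme.rare_threshold)
    if not eligible:
        raise ValueError(f"no eligible variants for gene {scheme.gene!r}")
    rows = catalog.loc[catalog["variant_id"].isin(eligible)]
    mapping: dict[str, str] = {}
    for _, row in rows.iterrows():
        hits = [lab for lab, cond in scheme.categories if _eval_condition(cond, row)]
        if len(hits) != 1:
            raise PartitionError(
                f"variant {row['variant_id']!r} matched {len(hits)} categories "
                f"({hits}) in scheme for {scheme.gene}"
            )
        mapping[row["variant_id"]] = hits[0]
    return GroupAssignment(scheme.gene, mapping, scheme)


# ---------------------------------------------------------------------------
# built-in schemes
# ---------------------------------------------------------------------------

def builtin_scheme(gene: str, kind: str = "standard",
                   cadd_q5_boundary: float = ATM_CADD_Q5_BOUNDARY) -> RiskGroupScheme:
    """Return a published per-gene scheme.

    ``kind`` is "standard" for the primary domain/score schemes, "sge" for the
    layered BRCA1 saturation-genome-editing scheme, or "hdr" for the layered
    BRCA2 homology-directed-repair scheme.  For ATM the CADD quintile-5
    boundary defaults to the published value but may be replaced by one
    computed from training data via :func:`quantile_boundaries`.
    """
    key = (gene.upper(), kind)
    helix_high = {"score_gt": {"score": "helix", "value": HELIX_CUT}}
    helix_low = {"score_le": {"score": "helix", "value": HELIX_CUT}}
    if key == ("ATM", "standard"):
        fatpik = ["FAT", "PIK"]
        return RiskGroupScheme(
            gene="ATM",
            baseline_label="outside_FAT_PIK",
            params={"cadd_q5_boundary": cadd_q5_boundary},
            categories=[
                ("outside_FAT_PIK", {"domain_not_in": fatpik}),
                ("FAT_PIK_CADD1-4", {"domain_in": fatpik,
                                     "score_le": {"score": "cadd", "value": cadd_q5_boundary}}),
                ("FAT_PIK_CADD5", {"domain_in": fatpik,
                                   "score_gt": {"score": "cadd", "value": cadd_q5_boundary}}),
            ],
        )
    if key == ("BRCA1", "standard"):
        dom = ["RING", "BRCT"]
        return RiskGroupScheme(
            gene="BRCA1",
            baseline_label="outside_RING_BRCT",
            categories=[
                ("outside_RING_BRCT", {"domain_not_in": dom}),
                ("RING_BRCT_Helix-low", {"domain_in": dom, **helix_low}),
                ("RING_BRCT_Helix-high", {"domain_in": dom, **helix_high}),
            ],
        )
    if key in (("BRCA2", "standard"), ("CHEK2", "standard")):
        return RiskGroupScheme(
            gene=key[0],
            baseline_label="Helix-low",
            categories=[("Helix-low", helix_low), ("Helix-high", helix_high)],
        )
    if key == ("PALB2", "standard"):
        return RiskGroupScheme(
            gene="PALB2",
            baseline_label="carriers",
            categories=[("carriers", {"match_all": True})],
        )
    if key == ("BRCA1", "sge"):
        dom = ["RING", "BRCT"]
        missing = {"class_in": {"field": "sge_class", "values": ["NA"]}}
        return RiskGroupScheme(
            gene="BRCA1",
            baseline_label="FUNC_SGE_or_outside",
            categories=[
                ("INT_LOF_SGE", {"class_in": {"field": "sge_class", "values": ["LOF", "INT"]}}),
                ("RING_BRCT_Helix-high_noSGE", {**missing, "domain_in": dom, **helix_high}),
                ("RING_BRCT_Helix-low_noSGE", {**missing, "domain_in": dom, **helix_low}),
                ("FUNC_SGE_or_outside",
                 {"any": [{"class_in": {"field": "sge_class", "values": ["FUNC"]}},
                          {**missing, "domain_not_in": dom}]}),
            ],
        )
    if key == ("BRCA2", "hdr"):
        missing = {"class_in": {"field": "hdr_class", "values": ["NA"]}}
        return RiskGroupScheme(
            gene="BRCA2",
            baseline_label="LB_B_HDR",
            categories=[
                ("LP_P_HDR", {"class_in": {"field": "hdr_class", "values": ["LP_P"]}}),
                ("Helix-high_unassayed", {**missing, **helix_high}),
                ("Helix-low_unassayed", {**missing, **helix_low}),
                ("LB_B_HDR", {"class_in": {"field": "hdr_class", "values": ["LB_B"]}}),
            ],
        )
    raise ValueError(f"no built-in scheme for gene={gene!r}, kind={kind!r}")
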