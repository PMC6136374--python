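"""DEG calling and ABA-dependence classification of drought-responsive genes.

A gene is a DEG in a contrast when its absolute fold change is at least
``min_fold_change`` (i.e. ``|log2FC| >= log2(min_fold_change)``, boundary
inclusive) and its p-value is strictly below ``max_p``. Drought-responsive
genes (DEG after 10 or 12 days of drought) are partitioned into:

* ``ABA_DEPENDENT``   — also a DEG under exogenous ABA treatment, and
  recovered by rewatering (not a DEG in the rewatered contrast);
* ``ABA_INDEPENDENT`` — not a DEG under ABA, recovered by rewatering;
* ``NOT_RECOVERED``   — still differentially expressed after rewatering;
  these genes are discarded from downstream crosstalk analyses;
* ``NON_DEG``         — everything else.

Also provides the sequencing-depth saturation curve, 2^-ddCt relative
expression, and Pearson concordance between quantification methods.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CONTRASTS",
    "DegClass",
    "DegThresholds",
    "DdctMeasurement",
    "call_contrast_degs",
    "classify_degs",
    "class_counts",
    "saturation_curve",
    "ddct_relative_expression",
    "method_concordance",
]

logger = logging.getLogger(__name__)

#: Experimental contrasts, each treatment vs its own control:
#: drought day 10, drought day 12, rewatered 2 days, ABA spray 4 h.
CONTRASTS = ("drought10", "drought12", "rewater2", "aba4")


class DegClass(str, Enum):
    ABA_DEPENDENT = "ABA_DEPENDENT"
    ABA_INDEPENDENT = "ABA_INDEPENDENT"
    NOT_RECOVERED = "NOT_RECOVERED"
    NON_DEG = "NON_DEG"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class DegThresholds:
    """DEG calling thresholds: fold change >= 2 (inclusive), p < 0.05 (strict)."""

    min_fold_change: float = 2.0
    max_p: float = 0.05

    def __post_init__(self) -> None:
        if not self.min_fold_change > 1:
            raise ValueError(f"min_fold_change must be > 1, got {self.min_fold_change}")
        if not 0 < self.max_p < 1:
            raise ValueError(f"max_p must be in (0, 1), got {self.max_p}")

    @property
    def min_abs_log2fc(self) -> float:
        return math.log2(self.min_fold_change)


def _validate_table(table: pd.DataFrame, contrasts=CONTRASTS) -> None:
    for c in contrasts:
        for col in (f"log2fc_{c}", f"p_{c}"):
            if col not in table.columns:
                raise ValueError(f"contrast table is missing column '{col}'")
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene_ids in contrast table: {dups[:5]}")
    for c in contrasts:
        p = table[f"p_{c}"]
        bad = p.dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValueError(f"p-values outside [0, 1] in contrast '{c}'")


def _deg_mask(table: pd.DataFrame, contrast: str, thresholds: DegThresholds) -> pd.Series:
    """Boolean DEG status per gene; missing values are never DEGs."""
    lfc = table[f"log2fc_{contrast}"]
    p = table[f"p_{contrast}"]
    missing = lfc.isna() | p.isna()
    n_missing = int(missing.sum())
    if n_missing:
        logger.warning(
            "contrast '%s': %d gene(s) with missing values excluded from DEG call",
            contrast, n_missing,
        )
    return (lfc.abs() >= thresholds.min_abs_log2fc) & (p < thresholds.max_p) & ~missing


def call_contrast_degs(
    table: pd.DataFrame,
    contrast: str,
    thresholds: DegThresholds = DegThresholds(),
) -> set:
    """Gene ids passing the DEG thresholds in one contrast."""
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast '{contrast}'; expected one of {CONTRASTS}")
    _validate_table(table, contrasts=(contrast,))
    return set(table.index[_deg_mask(table, contrast, thresholds)])


def classify_degs(
    table: pd.DataFrame,
    thresholds: DegThresholds = DegThresholds(),
    require_concordant_sign: bool = False,
) -> pd.Series:
    """Partition every gene into one of the four DEG classes.

    Returns a :class:`pandas.Series` of class labels indexed by gene_id;
    the labels always form an exact partition of the input genes.

    With ``require_concordant_sign`` (off by default), ABA dependence
    additionally requires the ABA-contrast fold change to agree in sign
    with at least one qualifying drought contrast; discordant genes are
    classified ABA_INDEPENDENT.
    """
    _validate_table(table)
    deg = {c: _deg_mask(table, c, thresholds) for c in CONTRASTS}
    drought = deg["drought10"] | deg["drought12"]
    recovered = ~deg["rewater2"]
    aba = deg["aba4"]

    if require_concordant_sign:
        sign_aba = np.sign(table["log2fc_aba4"])
        concordant = pd.Series(False, index=table.index)
        for c in ("drought10", "drought12"):
            concordant |= deg[c] & (np.sign(table[f"log2fc_{c}"]) == sign_aba)
        aba = aba & concordant

    classes = pd.Series(DegClass.NON_DEG.value, index=table.index, name="deg_class")
    classes[drought & ~recovered] = DegClass.NOT_RECOVERED.value
    classes[drought & recovered & aba] = DegClass.ABA_DEPENDENT.value
    classes[drought & recovered & ~aba] = DegClass.ABA_INDEPENDENT.value
    logger.info("classify_degs: %s", class_counts(classes))
    return classes


def class_counts(classes: pd.Series) -> dict:
    """Count of genes in each DEG class (all four classes always present)."""
    vc = classes.value_counts()
    return {c.value: int(vc.get(c.value, 0)) for c in DegClass}


def class_gene_sets(classes: pd.Series) -> dict:
    """Gene-id sets per class, for feeding the network enrichment stage."""
    return {c.value: set(classes.index[classes == c.value]) for c in DegClass}


# ----------------------------------------------------------------------
# QC: sequencing-depth saturation
# ----------------------------------------------------------------------
def saturation_curve(
    read_counts,
    depths,
    min_reads: int = 5,
    n_reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Detected-gene count as a function of subsampled sequencing depth.

    Reads are subsampled without replacement from the per-gene count
    vector (multivariate hypergeometric draw); a gene counts as detected
    when its subsampled count is at least ``min_reads``. The curve is
    averaged over ``n_reps`` draws per depth.
    """
    counts = np.asarray(read_counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("read counts must be non-negative")
    total = int(counts.sum())
    depths = [int(d) for d in depths]
    for d in depths:
        if d > total:
            raise ValueError(f"subsample depth {d} exceeds library size {total}")
        if d < 0:
            raise ValueError("depths must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for d in depths:
        detected = np.empty(n_reps, dtype=np.int64)
        for r in range(n_reps):
            if d == total:
                sub = counts  # full library: the subsample is the library
            else:
                sub = rng.multivariate_hypergeometric(counts, d, method="marginals")
            detected[r] = int((sub >= min_reads).sum())
        rows.append(
            {"depth": d, "mean_detected": float(detected.mean()),
             "sd_detected": float(detected.std(ddof=1)) if n_reps > 1 else 0.0}
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# validation computations
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class DdctMeasurement:
    """Cycle-threshold quadruple for one gene/sample pair in qRT-PCR."""

    ct_target_treated: float
    ct_ref_treated: float
    ct_target_control: float
    ct_ref_control: float

    def __post_init__(self) -> None:
        for f in (self.ct_target_treated, self.ct_ref_treated,
                  self.ct_target_control, self.ct_ref_control):
            if not math.isfinite(f):
                raise ValueError("all Ct values must be finite")

    @property
    def ddct(self) -> float:
        return (self.ct_target_treated - self.ct_ref_treated) - (
            self.ct_target_control - self.ct_ref_control
        )


def ddct_relative_expression(m: DdctMeasurement) -> float:
    """Relative expression by the 2^-ddCt method."""
    return float(2.0 ** (-m.ddct))


def method_concordance(x, y) -> tuple[float, float]:
    """Pearson correlation between paired log2 fold changes of two methods.

    Returns ``(r, p)`` with the standard two-sided t-distributed p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
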