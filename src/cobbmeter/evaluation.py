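"""Observer-agreement statistics for Cobb-angle measurements.

The package ships a 70-image fixture of Cobb angles measured three ways on
the same radiographs: by a scoliosis-specialist neurosurgeon (``obs1``, the
reference), by a second neurosurgeon (``obs2``), and by the automated
pipeline (``auto``).  Images are stratified by curve severity: below 10
degrees, 10-25, above 25 to 40, and above 40.

Agreement of a comparator against the reference is summarized by the
per-image percentage accuracy

    accuracy = 100 - 100 * |ref - test| / ref,

the signed measurement difference (test - ref), the share of images within a
clinical +/-5 degree band, and by intraclass and Pearson correlation.  Only
raw angle columns are stored; every derived statistic is recomputed here.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["MeasurementRecord", "AgreementSummary", "STRATA",
           "percentage_accuracy", "load_fixture_records", "records_frame",
           "summarize", "icc", "pearson", "compare_groups",
           "FIXTURE_SHA256"]

STRATA = ("<10", "10-25", ">25-40", ">40")

#: Checksum of the packaged raw-measurement fixture (guards against edits).
FIXTURE_SHA256 = "0ed30af0d3e0db27f43751fd736fad8f07055602cefeef6f0b53a69b0f318ae5"


@dataclass(frozen=True)
class MeasurementRecord:
    """One image's three Cobb readings and its severity stratum."""

    image_id: int
    obs1: int
    obs2: int
    auto: int
    stratum: str

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if min(self.obs1, self.obs2, self.auto) < 0:
            raise ValueError("angles must be non-negative")


@dataclass(frozen=True)
class AgreementSummary:
    comparator: str
    n_total: int
    median_accuracy: float
    iqr_accuracy: tuple[float, float]
    median_diff: float
    iqr_diff: tuple[float, float]
    n_within: int
    tolerance_deg: float

    @property
    def pct_within(self) -> float:
        return 100.0 * self.n_within / self.n_total


def percentage_accuracy(ref: float, test: float) -> float:
    """Percentage accuracy of ``test`` against reference ``ref``.

    100 - 100 * |ref - test| / ref; negative when the error exceeds the
    reference, deliberately not clipped.
    """
    if ref == 0:
        raise ZeroDivisionError("percentage accuracy undefined for a zero reference")
    return 100.0 - 100.0 * abs(ref - test) / ref


def load_fixture_records() -> list[MeasurementRecord]:
    """The packaged 70-image measurement set (raw angles only)."""
    ref = resources.files("cobbmeter.data") / "cobb_measurements.csv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != FIXTURE_SHA256:
        raise RuntimeError(
            f"measurement fixture checksum mismatch ({digest}); reinstall the package")
    df = pd.read_csv(ref)
    return [MeasurementRecord(int(r.image_id), int(r.obs1), int(r.obs2),
                              int(r.auto), str(r.stratum))
            for r in df.itertuples(index=False)]


def records_frame(records: list[MeasurementRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def _quartiles(x: np.ndarray) -> tuple[float, float]:
    # linear interpolation between order statistics
    return (float(np.percentile(x, 25)), float(np.percentile(x, 75)))


def summarize(records: list[MeasurementRecord], comparator: str = "auto",
              tolerance_deg: float = 5.0) -> AgreementSummary:
    """Accuracy / difference / within-band summary against the reference."""
    if comparator not in ("auto", "obs2"):
        raise ValueError("comparator must be 'auto' or 'obs2'")
    if not records:
        raise ValueError("cannot summarize an empty record set")
    ref = np.array([r.obs1 for r in records], dtype=float)
    test = np.array([getattr(r, comparator) for r in records], dtype=float)
    acc = 100.0 - 100.0 * np.abs(ref - test) / ref
    diff = test - ref
    return AgreementSummary(
        comparator=comparator,
        n_total=len(records),
        median_accuracy=float(np.median(acc)),
        iqr_accuracy=_quartiles(acc),
        median_diff=float(np.median(diff)),
        iqr_diff=_quartiles(diff),
        n_within=int((np.abs(diff) <= tolerance_deg).sum()),
        tolerance_deg=tolerance_deg,
    )


def icc(a, b, form: str = "single") -> float:
    """Two-way random-effects, absolute-agreement intraclass correlation.

    ``form='single'`` returns ICC(2,1), the agreement of one rating;
    ``form='average'`` returns ICC(2,k), the agreement of the k-rater mean.
    """
    import pingouin as pg

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1-D samples of length >= 3")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("zero variance: ICC undefined")
    n = len(a)
    df = pd.DataFrame({
        "target": np.tile(np.arange(n), 2),
        "rater": np.repeat(["a", "b"], n),
        "rating": np.concatenate([a, b]),
    })
    table = pg.intraclass_corr(df, targets="target", raters="rater",
                               ratings="rating")
    key = "ICC(A,1)" if form == "single" else "ICC(A,k)"
    return float(table.loc[table["Type"] == key, "ICC"].iloc[0])


def pearson(a, b) -> float:
    """Pearson product-moment correlation."""
    from scipy.stats import pearsonr

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need two equal-length samples of length >= 3")
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(pearsonr(a, b)[0])


def compare_groups(x, y, kind: str) -> tuple[float, float]:
    """Two-sided group comparison: Mann-Whitney U or 2x2 chi-square.

    Mann-Whitney uses the tie-corrected normal approximation; the chi-square
    test applies no continuity correction.  Returns (statistic, p).
    """
    from scipy import stats

    if kind == "mann_whitney":
        res = stats.mannwhitneyu(np.asarray(x, float), np.asarray(y, float),
                                 alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    if kind == "chi_square":
        table = np.asarray(x if y is None else [x, y], dtype=float)
        if table.shape != (2, 2):
            raise ValueError("chi-square expects a 2x2 count table")
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise ValueError("degenerate table: a margin is zero")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), float(p)
    raise ValueError(f"unknown test kind {kind!r}")
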