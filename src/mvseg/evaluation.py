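"""Volumetric and spatial agreement statistics.

Spatial agreement is the Dice similarity coefficient DSC = 2|A∩B|/(|A|+|B|);
volumetric agreement is the two-way intraclass correlation for absolute
agreement, single measure (ICC(A,1)) between reference and predicted
volumes. Paired DSC comparisons between models use the two-sided Wilcoxon
signed-rank test with Bonferroni correction, and tumor results can be
stratified into size terciles.

A DSC where both masks are empty is *undefined* and reported as ``None``
(excluded from summaries, with the count logged by the caller); a missed
structure that exists in the reference gives DSC = 0, which is defined and
included. The "eye" entry is the union of all non-background classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import CLASS_NAMES, LabelMap

EYE_CLASSES = tuple(range(1, 6))  # sclera..tumor union


@dataclass(frozen=True)
class MaskPair:
    """Reference (A) and predicted (B) binary masks on one grid."""

    A: np.ndarray
    B: np.ndarray
    voxel_volume_mm3: float = 1.0

    def dice(self) -> float | None:
        return dice(self.A, self.B)

    def volumes_mL(self) -> tuple[float, float]:
        return (
            volume_mL(self.A, self.voxel_volume_mm3),
            volume_mL(self.B, self.voxel_volume_mm3),
        )


def dice(a: np.ndarray, b: np.ndarray) -> float | None:
    """Dice similarity coefficient; ``None`` when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return None
    return 2.0 * int((a & b).sum()) / (na + nb)


def volume_mL(mask: np.ndarray, voxel_volume_mm3: float) -> float:
    """Mask volume in millilitres (1 mL = 1000 mm^3)."""
    if voxel_volume_mm3 <= 0:
        raise ValueError("voxel volume must be positive")
    return int(np.asarray(mask, dtype=bool).sum()) * voxel_volume_mm3 / 1000.0


def icc_single_absolute(pairs) -> float | None:
    """ICC(A,1): two-way model, absolute agreement, single measure.

    ``pairs`` is an ``(n, 2)`` table of (reference, prediction) values, one
    row per eye. Returns ``None`` when there is no between-subject variance
    (the coefficient is undefined).
    """
    x = np.asarray(pairs, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != 2 or x.shape[0] < 2:
        raise ValueError("need an (n >= 2, 2) table of paired measurements")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    if np.allclose(row_means.var(), 0.0):
        return None
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return float(
        (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    )


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_raw: float
    p_corrected: float
    n_used: int  # pairs remaining after zero-difference removal


def wilcoxon_bonferroni(
    dsc_a, dsc_b, m: int = 6
) -> WilcoxonResult | None:
    """Two-sided Wilcoxon signed-rank test on paired DSC, Bonferroni-corrected.

    Zero differences are discarded (classic Wilcoxon); the exact null
    distribution is used for n <= 25, otherwise the normal approximation
    with continuity correction. ``m`` is the number of comparisons (default:
    the 6 classes); corrected p = min(1, m * p). Returns ``None`` when every
    difference is zero (the test is undefined).
    """
    a = np.asarray(dsc_a, dtype=np.float64)
    b = np.asarray(dsc_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return None
    if d.size < 5:
        raise ValueError("fewer than 5 non-zero paired differences")
    method = "exact" if d.size <= 25 else "approx"
    res = stats.wilcoxon(
        d,
        zero_method="wilcox",
        correction=(method == "approx"),
        method=method,
        alternative="two-sided",
    )
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        p_corrected=min(1.0, m * float(res.pvalue)),
        n_used=int(d.size),
    )


def tercile_groups(tumor_volumes) -> np.ndarray:
    """Group tumor volumes into small / medium / large terciles.

    Cut points are the 33⅓ and 66⅔ linear-interpolation percentiles of the
    reference volumes; a value equal to a cut point falls in the lower
    group (so all-equal inputs land in a single "small" group).
    """
    v = np.asarray(tumor_volumes, dtype=np.float64)
    if v.size < 3:
        raise ValueError("need at least 3 volumes for terciles")
    q1, q2 = np.percentile(v, [100.0 / 3.0, 200.0 / 3.0], method="linear")
    out = np.full(v.shape, "large", dtype=object)
    out[v <= q2] = "medium"
    out[v <= q1] = "small"
    return out


# ---------------------------------------------------------------------------
# per-fold bookkeeping

@dataclass(frozen=True)
class ClassMetrics:
    dsc: float | None
    reference_mL: float
    predicted_mL: float


@dataclass
class FoldResult:
    """Per-eye, per-class agreement for one cross-validation fold."""

    subject: str
    eye: str
    metrics: dict[str, ClassMetrics] = field(default_factory=dict)


def evaluate_prediction(
    reference: LabelMap, predicted: LabelMap, subject: str, eye: str = "eye0"
) -> FoldResult:
    """DSC and volumes (mL) per class plus the whole-eye class union."""
    if reference.shape != predicted.shape:
        raise ValueError("reference and prediction grids differ")
    vv = reference.voxel_volume_mm3
    result = FoldResult(subject=subject, eye=eye)
    for idx, name in enumerate(CLASS_NAMES):
        if idx == 0:
            continue
        ref_m = reference.data == idx
        pred_m = predicted.data == idx
        result.metrics[name] = ClassMetrics(
            dsc=dice(ref_m, pred_m),
            reference_mL=volume_mL(ref_m, vv),
            predicted_mL=volume_mL(pred_m, vv),
        )
    ref_eye = np.isin(reference.data, EYE_CLASSES)
    pred_eye = np.isin(predicted.data, EYE_CLASSES)
    result.metrics["eye"] = ClassMetrics(
        dsc=dice(ref_eye, pred_eye),
        reference_mL=volume_mL(ref_eye, vv),
        predicted_mL=volume_mL(pred_eye, vv),
    )
    return result


def fold_table(folds: list[FoldResult]) -> pd.DataFrame:
    """Tidy per-eye, per-class table of DSC and volumes."""
    rows = []
    for f in folds:
        for cls, m in f.metrics.items():
            rows.append(
                {
                    "subject": f.subject,
                    "eye": f.eye,
                    "class": cls,
                    "dsc": np.nan if m.dsc is None else m.dsc,
                    "dsc_defined": m.dsc is not None,
                    "reference_mL": m.reference_mL,
                    "predicted_mL": m.predicted_mL,
                }
            )
    return pd.DataFrame(rows)


def summarize(folds: list[FoldResult]) -> pd.DataFrame:
    """Per-class mean ± sd and median [IQR] DSC, volume ICC, and the count
    of undefined (both-empty) DSCs excluded from the summaries."""
    table = fold_table(folds)
    rows = []
    for cls, sub in table.groupby("class", sort=False):
        d = sub.loc[sub["dsc_defined"], "dsc"].to_numpy()
        vols = sub[["reference_mL", "predicted_mL"]].to_numpy()
        icc = icc_single_absolute(vols) if len(vols) >= 2 else None
        rows.append(
            {
                "class": cls,
                "n": len(sub),
                "n_undefined_dsc": int((~sub["dsc_defined"]).sum()),
                "dsc_mean": d.mean() if d.size else np.nan,
                "dsc_sd": d.std(ddof=1) if d.size > 1 else np.nan,
                "dsc_median": np.median(d) if d.size else np.nan,
                "dsc_q1": np.percentile(d, 25) if d.size else np.nan,
                "dsc_q3": np.percentile(d, 75) if d.size else np.nan,
                "volume_icc": np.nan if icc is None else icc,
            }
        )
    return pd.DataFrame(rows).set_index("class")
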