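"""Segmentation and agreement metrics.

Covers the two mask-level accuracy measures (intersection over union and
bottom-edge RMS) and the inter-rater agreement statistics used to compare
manual and automated minimum-foot-clearance estimates: per-pedestrian RMS
versus the rater mean, the aggregate RMS (the arithmetic mean of the
per-pedestrian values), and Bland-Altman bias with 95% limits of
agreement.

A reference inter-rater table ships with the package: manual MFC (mm)
mean, standard deviation and RMS-vs-mean for ten pedestrians measured by
five raters in a sidewalk field study, alongside the automated system's
per-pedestrian RMS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd

from .footwear import FootwearMask

logger = logging.getLogger(__name__)


def mask_iou(a: np.ndarray | FootwearMask, b: np.ndarray | FootwearMask) -> float:
    """Intersection over union of two binary masks on the same grid.

    Both empty counts as perfect agreement (1.0); exactly one empty is
    complete disagreement (0.0).
    """
    am = a.mask if isinstance(a, FootwearMask) else np.asarray(a, dtype=bool)
    bm = b.mask if isinstance(b, FootwearMask) else np.asarray(b, dtype=bool)
    if am.shape != bm.shape:
        raise ValueError(f"mask shapes differ: {am.shape} vs {bm.shape}")
    union = np.logical_or(am, bm).sum()
    if union == 0:
        return 1.0
    inter = np.logical_and(am, bm).sum()
    return float(inter / union)


@dataclass(frozen=True)
class BottomEdgeError:
    """Bottom-edge RMS over shared columns plus a coverage statistic."""

    rms_px: float | None
    n_shared_columns: int
    coverage: float  # shared columns / union of occupied columns

    @property
    def valid(self) -> bool:
        return self.rms_px is not None


def bottom_edge_rms(detected: FootwearMask, truth: FootwearMask) -> BottomEdgeError:
    """RMS row error of the detected bottom edge against the truth edge.

    Computed over columns occupied by both masks; columns present in only
    one mask are excluded and reflected in ``coverage``.  No shared
    columns yields an invalid (flagged) result rather than an exception.
    """
    det = {int(c): int(r) for c, r in detected.bottom_edge}
    tru = {int(c): int(r) for c, r in truth.bottom_edge}
    shared = sorted(det.keys() & tru.keys())
    union = len(det.keys() | tru.keys())
    coverage = len(shared) / union if union else 0.0
    if not shared:
        logger.warning("bottom_edge_rms: no shared columns between masks")
        return BottomEdgeError(None, 0, coverage)
    diffs = np.array([det[c] - tru[c] for c in shared], dtype=float)
    return BottomEdgeError(float(np.sqrt(np.mean(diffs**2))), len(shared), coverage)


def rater_rms(measurements) -> tuple[float, float, float]:
    """Mean, sample SD and RMS-vs-mean of one pedestrian's rater values.

    The RMS deviation from the rater mean uses divisor ``n`` while the
    sample SD uses ``n - 1``, so ``rms = sd * sqrt((n - 1) / n)``.
    """
    values = np.asarray(measurements, dtype=float)
    if values.size < 2:
        raise ValueError("at least two rater values are required")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    rms = float(np.sqrt(np.mean((values - mean) ** 2)))
    return mean, sd, rms


def aggregate_rms(per_pedestrian_rms) -> float:
    """Overall RMS: the arithmetic mean of per-pedestrian RMS values."""
    values = np.asarray(per_pedestrian_rms, dtype=float)
    if values.size == 0:
        raise ValueError("empty RMS list")
    return float(values.mean())


@dataclass(frozen=True)
class BlandAltman:
    """Bias and 95% limits of agreement for paired measurements."""

    bias: float
    loa_lower: float
    loa_upper: float
    sd_diff: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman_stats(a, b) -> BlandAltman:
    """Bland-Altman agreement between two paired measurement lists.

    Differences are ``a - b``; limits are ``bias +/- 1.96 * SD`` of the
    differences (sample SD).  Constant differences give zero-width limits,
    which is valid.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equally sized lists with >= 2 pairs")
    diffs = a - b
    means = (a + b) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        sd_diff=sd,
        means=means,
        diffs=diffs,
    )


@dataclass
class AgreementReport:
    """Per-pedestrian and aggregate inter-rater agreement."""

    per_pedestrian: pd.DataFrame  # columns: mean, sd, rms
    aggregate_rms: float
    bland_altman: BlandAltman

    def to_json_dict(self) -> dict:
        return {
            "per_pedestrian": self.per_pedestrian.to_dict(orient="index"),
            "aggregate_rms": self.aggregate_rms,
            "bland_altman": {
                "bias": self.bland_altman.bias,
                "loa_lower": self.bland_altman.loa_lower,
                "loa_upper": self.bland_altman.loa_upper,
                "sd_diff": self.bland_altman.sd_diff,
            },
        }


def agreement_report(table: pd.DataFrame) -> AgreementReport:
    """Agreement statistics for a rater table.

    ``table``: one row per pedestrian, one column per rater (mm); at
    least two raters.  Bland-Altman statistics are pooled over all rater
    pairs.
    """
    if table.shape[1] < 2:
        raise ValueError("agreement statistics require at least two raters")
    if (table.to_numpy() < 0).any():
        raise ValueError("MFC measurements cannot be negative")
    rows = {}
    for ped, values in table.iterrows():
        mean, sd, rms = rater_rms(values.to_numpy())
        rows[ped] = {"mean": mean, "sd": sd, "rms": rms}
    per_ped = pd.DataFrame.from_dict(rows, orient="index")
    agg = aggregate_rms(per_ped["rms"].to_numpy())
    diffs, means = [], []
    for ca, cb in combinations(table.columns, 2):
        stats = bland_altman_stats(table[ca].to_numpy(), table[cb].to_numpy())
        diffs.append(stats.diffs)
        means.append(stats.means)
    diffs = np.concatenate(diffs)
    means = np.concatenate(means)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    pooled = BlandAltman(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        sd_diff=sd,
        means=means,
        diffs=diffs,
    )
    return AgreementReport(per_pedestrian=per_ped, aggregate_rms=agg,
                           bland_altman=pooled)


def load_rater_study() -> pd.DataFrame:
    """The packaged reference inter-rater study table.

    Ten pedestrians, indexed 1-10: manual MFC mean, sample SD and
    RMS-vs-mean (five raters), plus the automated system's RMS, all in
    mm.
    """
    with resources.files("footclear.data").joinpath("rater_study.csv").open() as fh:
        return pd.read_csv(fh, index_col="pedestrian")


def read_rater_table(path) -> pd.DataFrame:
    """Read a rater table CSV: first column pedestrian id, one column per rater."""
    return pd.read_csv(path, index_col=0)
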