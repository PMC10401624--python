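"""Jumper vs. non-jumper comparisons: fold changes, PCA, leg ratios.

The study design pairs each jumping species with a closely related
non-jumping one and compares size-normalized metrics directly; a PCA of
centered-and-scaled absolute muscle and thorax volumes summarizes the
multivariate separation between the two groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ValidationError
from .units import round_half_up

__all__ = [
    "fold_change",
    "PairComparison",
    "pair_comparisons",
    "extensor_flexor_ratio",
    "LegRatioResult",
    "leg_ratios",
    "PcaResult",
    "run_pca",
    "pc1_separation",
]


def fold_change(jumper_value: float, nonjumper_value: float) -> float:
    """Ratio of a jumper's metric to its non-jumping counterpart's.

    Both values must be computed under identical normalization;
    fold_change(a, b) * fold_change(b, a) == 1.
    """
    if not (jumper_value > 0 and nonjumper_value > 0):
        raise ValidationError("fold change requires two positive values")
    return jumper_value / nonjumper_value


@dataclass(frozen=True)
class PairComparison:
    jumper: str
    nonjumper: str
    muscle_code: str
    fold_change: float


def pair_comparisons(
    jumper_metrics: dict[str, float],
    nonjumper_metrics: dict[str, float],
    jumper: str,
    nonjumper: str,
) -> list[PairComparison]:
    """Per-muscle fold changes for one species pair.

    Both dicts map muscle_code -> metric under the same normalization; the
    muscle sets must coincide.
    """
    if set(jumper_metrics) != set(nonjumper_metrics):
        only_j = sorted(set(jumper_metrics) - set(nonjumper_metrics))
        only_n = sorted(set(nonjumper_metrics) - set(jumper_metrics))
        raise ValidationError(
            f"mismatched muscle codes: jumper-only {only_j}, non-jumper-only {only_n}"
        )
    return [
        PairComparison(
            jumper=jumper,
            nonjumper=nonjumper,
            muscle_code=code,
            fold_change=fold_change(jumper_metrics[code], nonjumper_metrics[code]),
        )
        for code in sorted(jumper_metrics)
    ]


def extensor_flexor_ratio(
    ftm1_volume_m3: float, ftm2_volume_m3: float
) -> tuple[float, str]:
    """Tibial extensor (ftm1) over tibial flexor (ftm2) volume.

    Ratios >= 1 are characteristic of walking legs; ratios < 1 of grasping
    legs, the typical insect condition.
    """
    if not (ftm1_volume_m3 > 0 and ftm2_volume_m3 > 0):
        raise ValidationError("both muscle volumes must be > 0")
    ratio = ftm1_volume_m3 / ftm2_volume_m3
    label = "walking-leg-like" if ratio >= 1 else "grasping-leg-like"
    return ratio, label


@dataclass(frozen=True)
class LegRatioResult:
    """Leg lengths relative to the shortest leg, plus hind leg % body length.

    ``ratio_*`` fields are display-rounded (shortest leg = 1); the
    ``raw_*`` fields keep full precision.
    """

    species_name: str
    ratio_front: float
    ratio_middle: float
    ratio_hind: float
    hind_pct_body: int
    raw_front: float
    raw_middle: float
    raw_hind: float
    raw_hind_pct_body: float

    @property
    def ratio_string(self) -> str:
        """E.g. ``'1:1.1:1.6'`` (front:middle:hind), trailing .0 dropped."""

        def fmt(x: float) -> str:
            return str(int(x)) if float(x).is_integer() else f"{x:g}"

        return f"{fmt(self.ratio_front)}:{fmt(self.ratio_middle)}:{fmt(self.ratio_hind)}"


def leg_ratios(
    front_mm: float,
    middle_mm: float,
    hind_mm: float,
    body_length_mm: float,
    species_name: str = "",
    decimals: int = 1,
) -> LegRatioResult:
    """Normalize leg lengths to the shortest leg and to body length.

    The shortest of the three legs is the reference (ratio exactly 1); the
    other ratios are rounded half-up to ``decimals`` for display, and the
    hind-leg percentage of body length is rounded to an integer.
    """
    for name, v in {
        "front_mm": front_mm,
        "middle_mm": middle_mm,
        "hind_mm": hind_mm,
        "body_length_mm": body_length_mm,
    }.items():
        if not (v > 0):
            raise ValidationError(f"{name} must be > 0, got {v!r}")
    shortest = min(front_mm, middle_mm, hind_mm)
    raw = (front_mm / shortest, middle_mm / shortest, hind_mm / shortest)
    raw_pct = 100.0 * hind_mm / body_length_mm
    rounded = tuple(round_half_up(r, decimals) for r in raw)
    return LegRatioResult(
        species_name=species_name,
        ratio_front=rounded[0],
        ratio_middle=rounded[1],
        ratio_hind=rounded[2],
        hind_pct_body=int(round_half_up(raw_pct, 0)),
        raw_front=raw[0],
        raw_middle=raw[1],
        raw_hind=raw[2],
        raw_hind_pct_body=raw_pct,
    )


@dataclass(frozen=True)
class PcaResult:
    """PCA of the centered-and-scaled species x variables volume matrix."""

    variable_names: list[str]
    species_names: list[str]
    scores: np.ndarray  # (n_species, n_components)
    loadings: np.ndarray  # (n_variables, n_components), orthonormal columns
    variance_explained: np.ndarray  # fractions, non-increasing, sum 1

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.species_names, columns=cols)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=self.variable_names, columns=cols)


def run_pca(matrix: pd.DataFrame) -> PcaResult:
    """PCA on z-scored absolute volumes (species rows x variable columns).

    Columns are centered and scaled to unit sample variance, then the
    covariance matrix of the standardized data is eigen-decomposed
    (equivalent to a correlation-matrix PCA). Component signs are fixed so
    that each loading vector's largest-magnitude entry is positive.
    """
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(matrix)
    if matrix.shape[0] < 3:
        raise ValidationError(f"need >= 3 species rows, got {matrix.shape[0]}")
    if matrix.isna().any().any():
        bad = matrix.columns[matrix.isna().any()].tolist()
        raise ValidationError(f"missing cells in variable(s) {bad}")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    constant = [c for c, s in zip(matrix.columns, sd) if s == 0]
    if constant:
        raise ValidationError(f"constant variable(s): {constant}")
    z = (values - values.mean(axis=0)) / sd
    cov = np.cov(z, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-|entry| of each loading vector positive
    for j in range(eigvecs.shape[1]):
        k = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    return PcaResult(
        variable_names=[str(c) for c in matrix.columns],
        species_names=[str(i) for i in matrix.index],
        scores=z @ eigvecs,
        loadings=eigvecs,
        variance_explained=eigvals / eigvals.sum(),
    )


def pc1_separation(
    result: PcaResult, jumping_labels: dict[str, bool]
) -> tuple[bool, float]:
    """Does a single threshold on PC1 scores perfectly split the two groups?

    Returns (separated, margin) where margin is the gap between the groups'
    closest PC1 scores (0 when they overlap or interleave).
    """
    missing = [s for s in result.species_names if s not in jumping_labels]
    if missing:
        raise ValidationError(f"labels missing for species {missing}")
    labels = np.array([jumping_labels[s] for s in result.species_names])
    if labels.all() or not labels.any():
        raise ValidationError("need both jumping and non-jumping species")
    pc1 = result.scores[:, 0]
    jump, nonjump = pc1[labels], pc1[~labels]
    gap_right = nonjump.min() - jump.max()
    gap_left = jump.min() - nonjump.max()
    margin = max(gap_right, gap_left)
    return bool(margin > 0), float(max(margin, 0.0))
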