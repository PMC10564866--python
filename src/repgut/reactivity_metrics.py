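"""Antibody reactivity metrics: ELISA AUC summaries and the
protein-microarray polyreactivity index (PI).

ELISA binding curves are summarized by the trapezoidal area under
OD405 against log10(concentration); an antibody's polyreactivity over
an antigen panel is the cumulative AUC, CAUC = log10(sum AUC + 1), so a
zero-binding antibody sits at CAUC 0. Microarray profiles are scored as
robust per-array Z-scores (median/MAD); the deviation of each protein
from the test-vs-reference diagonal is sigma = (Z_test − Z_ref)/sqrt(2),
and PI is the fraction of proteins beyond the diagonal band
(sigma > 2). An antibody is polyreactive when PI > 0.21 (strict).

The PI functional form is a reconstruction preserving the published
threshold semantics (PI in [0, 1], cutoff 0.21); numerical parity with
the vendor scoring software is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

PI_THRESHOLD = 0.21
SIGMA_BAND = 2.0


@dataclass
class BindingCurve:
    """Background-subtracted ELISA dilution series for one antibody/antigen."""

    antibody_id: str
    antigen: str
    concentrations: np.ndarray  # strictly decreasing along the series
    od405: np.ndarray
    replicate_count: int = 1

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.od405 = np.asarray(self.od405, dtype=float)
        if len(self.concentrations) != len(self.od405):
            raise ValueError("concentration and OD series differ in length")
        if not np.all(np.diff(self.concentrations) < 0):
            raise ValueError("concentrations must be strictly decreasing")
        if not np.all(np.isfinite(self.od405)):
            raise ValueError("non-finite OD value")


def curve_auc(curve: BindingCurve) -> float:
    """Trapezoidal integral of OD405 over log10(concentration).

    Negative ODs are clamped to 0 before integration.
    """
    if len(curve.od405) < 2:
        raise ValueError("AUC needs at least 2 dilution points")
    x = np.log10(curve.concentrations)
    y = np.clip(curve.od405, 0.0, None)
    return float(np.trapezoid(y[::-1], x[::-1]))


def cumulative_auc(curves: Iterable[BindingCurve]) -> float:
    """CAUC = log10(sum of per-antigen AUCs + 1) across the panel."""
    aucs = [curve_auc(c) for c in curves]
    if not aucs:
        raise ValueError("empty antigen panel")
    return float(np.log10(sum(aucs) + 1.0))


@dataclass
class MicroarrayProfile:
    """Test-vs-reference microarray reactivity profile for one antibody."""

    antibody_id: str
    protein_ids: list
    mfi_test: np.ndarray  # duplicate spots already averaged
    mfi_ref: np.ndarray
    z_test: Optional[np.ndarray] = None
    z_ref: Optional[np.ndarray] = None
    sigma: Optional[np.ndarray] = None
    pi: Optional[float] = None
    polyreactive: Optional[bool] = None


def _robust_z(values: np.ndarray) -> np.ndarray:
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        raise ValueError("degenerate array: MAD is zero")
    return (values - med) / (1.4826 * mad)


def microarray_zscores(spots: pd.DataFrame, antibody_id: str = "test") -> MicroarrayProfile:
    """Robust per-array Z-scores from a raw spot table.

    Expects columns protein_id, mfi_test_rep1, mfi_test_rep2,
    mfi_ref_rep1, mfi_ref_rep2; duplicate spots are averaged before
    scoring, and each array (test, reference) is scored against its own
    median/MAD.
    """
    required = {"protein_id", "mfi_test_rep1", "mfi_test_rep2", "mfi_ref_rep1", "mfi_ref_rep2"}
    missing = required - set(spots.columns)
    if missing:
        raise ValueError(f"spot table lacks columns: {sorted(missing)}")
    mfi_test = spots[["mfi_test_rep1", "mfi_test_rep2"]].mean(axis=1).to_numpy()
    mfi_ref = spots[["mfi_ref_rep1", "mfi_ref_rep2"]].mean(axis=1).to_numpy()
    return MicroarrayProfile(
        antibody_id=antibody_id,
        protein_ids=list(spots["protein_id"]),
        mfi_test=mfi_test,
        mfi_ref=mfi_ref,
        z_test=_robust_z(mfi_test),
        z_ref=_robust_z(mfi_ref),
    )


def polyreactivity_index(
    profile: MicroarrayProfile,
    sigma_band: float = SIGMA_BAND,
    pi_threshold: float = PI_THRESHOLD,
) -> MicroarrayProfile:
    """Diagonal deviation, PI and the strict PI > 0.21 classification.

    sigma_i is the signed perpendicular deviation of (Z_ref_i, Z_test_i)
    from the identity diagonal; PI is the fraction of proteins with
    sigma_i > ``sigma_band``.
    """
    if profile.z_test is None or profile.z_ref is None:
        raise ValueError("profile lacks Z-scores; run microarray_zscores first")
    sigma = (profile.z_test - profile.z_ref) / np.sqrt(2.0)
    pi = float(np.mean(sigma > sigma_band))
    profile.sigma = sigma
    profile.pi = pi
    profile.polyreactive = pi > pi_threshold
    return profile


def reactivity_summary(profiles: Iterable[MicroarrayProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {
                "antibody_id": p.antibody_id,
                "n_proteins": len(p.protein_ids),
                "pi": p.pi,
                "polyreactive": p.polyreactive,
            }
        )
    return pd.DataFrame(rows)
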