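"""Shape-factor and truncated-cone muscle-volume estimators.

Both estimators take a length-normalized ACSA profile and a small amount of
cohort-level information and return a volume in mm^3.

Shape-factor method
    The dimensionless shape factor p = MV / (L * ACSA_max) is nearly constant
    within a muscle across a population (p = 1 for a cylinder, 1/3 for a
    cone).  Fitting stores the cohort mean p_avg and the cohort-average
    ACSA_max location; prediction returns
    p_avg * L * ACSA(cohort-average location).
    Sampling the ACSA at the *average* location rather than at each subject's
    own peak is what makes the method applicable in practice (one standard
    measurement site per muscle); an ``ideal`` mode substitutes the subject's
    own ACSA_max instead.

Truncated-cone method
    Five cross-sections are sampled: at 1% and 100% of muscle length, at the
    cohort-average ACSA_max location, and halfway between that location and
    each end slice.  The volume is the sum of the four conical-frustum
    segments d/3 * (A_i + A_{i+1} + sqrt(A_i * A_{i+1})).

Both classes follow the scikit-learn estimator API: ``fit`` consumes a
sequence of :class:`~musclevol.profile.AcsaProfile` plus (for the shape
factor) the slice-by-slice reference volumes, and ``predict`` maps profiles
to volume estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import NotFittedError

from .profile import AcsaProfile, acsa_at, find_acsa_max

__all__ = [
    "shape_factor",
    "ShapeFactorVolume",
    "TruncatedConeVolume",
    "TruncatedConeSampling",
    "truncated_cone_positions",
    "estimate_truncated_cone",
    "fit_shape_factor_model",
    "estimate_shape_factor",
]

#: The most distal sampled cross-section sits at 1% of muscle length, not 0%
#: (a zero-length end slice carries no measurable area).
DISTAL_SAMPLE = 0.01


def shape_factor(mv_ref_mm3: float, length_mm: float, acsa_max_mm2: float) -> float:
    """Dimensionless shape factor p = MV / (muscle length * ACSA_max).

    p characterizes how much of the bounding cylinder the muscle fills:
    exactly 1 for a cylinder and 1/3 for a cone, around 0.5-0.65 for human
    thigh muscles.  0 < p <= 1 whenever MV is the integral of areas bounded
    by ACSA_max over the length.
    """
    if mv_ref_mm3 <= 0 or length_mm <= 0 or acsa_max_mm2 <= 0:
        raise ValueError("volume, length and ACSA_max must all be positive")
    return mv_ref_mm3 / (length_mm * acsa_max_mm2)


@dataclass(frozen=True)
class TruncatedConeSampling:
    """The five sampled relative positions of the truncated-cone method.

    Positions descend from proximal to distal: x1 = 1.00 (ACSA_1),
    x2 = (1 + loc)/2, x3 = loc (the average ACSA_max location),
    x4 = (loc + 0.01)/2, x5 = 0.01 (ACSA_5).
    """

    positions: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions)
        if pos.shape != (5,):
            raise ValueError("exactly 5 positions required")
        if np.any(np.diff(pos) >= 0):
            raise ValueError("positions must be strictly decreasing")

    def distances_mm(self, length_mm: float) -> np.ndarray:
        """Inter-slice distances d_i = (x_i - x_{i+1}) * length, i = 1..4."""
        return -np.diff(np.asarray(self.positions)) * length_mm


def truncated_cone_positions(avg_location: float) -> TruncatedConeSampling:
    """Five-slice placement anchored at the cohort-average ACSA_max location."""
    if not DISTAL_SAMPLE < avg_location < 1.0:
        raise ValueError(
            f"average ACSA_max location must lie in ({DISTAL_SAMPLE}, 1.0), "
            f"got {avg_location}"
        )
    return TruncatedConeSampling(
        (
            1.0,
            (1.0 + avg_location) / 2.0,
            avg_location,
            (avg_location + DISTAL_SAMPLE) / 2.0,
            DISTAL_SAMPLE,
        )
    )


def estimate_truncated_cone(
    profile: AcsaProfile, sampling: TruncatedConeSampling
) -> float:
    """Sum of the four frustum segment volumes between the five sampled ACSAs."""
    areas = np.asarray([acsa_at(profile, x) for x in sampling.positions])
    assert np.all(areas >= 0), "interpolated areas cannot be negative"
    d = sampling.distances_mm(profile.length_mm)
    a0, a1 = areas[:-1], areas[1:]
    return float(np.sum(d / 3.0 * (a0 + a1 + np.sqrt(a0 * a1))))


def _as_profiles(X) -> list[AcsaProfile]:
    profiles = list(X)
    if not profiles or not all(isinstance(p, AcsaProfile) for p in profiles):
        raise ValueError("X must be a non-empty sequence of AcsaProfile")
    return profiles


class ShapeFactorVolume(RegressorMixin, BaseEstimator):
    """Shape-factor muscle-volume estimator.

    Parameters
    ----------
    ideal : bool, default False
        If True, prediction samples each subject's own ACSA_max instead of
        the ACSA at the cohort-average peak location.  The default is the
        in-practice variant, which needs only one standard measurement site.
    leave_one_out : bool, default False
        If True, ``fit_predict`` excludes each subject from the cohort
        averages used for that subject's own estimate.  Plain ``fit`` /
        ``predict`` always use the full-cohort averages (self-estimation).

    Attributes
    ----------
    p_ : ndarray of shape (n_subjects,)
        Per-subject shape factors MV / (L * ACSA_max).
    p_avg_ : float
        Cohort mean shape factor.
    p_sd_ : float
        Sample (n-1) standard deviation of the shape factors.
    locations_ : ndarray of shape (n_subjects,)
        Per-subject ACSA_max locations on the 1% grid.
    acsa_max_location_ : float
        Cohort mean ACSA_max location (fraction of muscle length, distal = 0).
    """

    def __init__(self, ideal: bool = False, leave_one_out: bool = False):
        self.ideal = ideal
        self.leave_one_out = leave_one_out

    def fit(self, X, y) -> "ShapeFactorVolume":
        """Fit cohort averages from profiles X and reference volumes y (mm^3)."""
        profiles = _as_profiles(X)
        y = np.asarray(y, dtype=float)
        if y.shape != (len(profiles),):
            raise ValueError("y must hold one reference volume per profile")
        if len(profiles) < 2:
            raise ValueError("at least 2 subjects are required to fit")
        if np.any(y <= 0):
            raise ValueError("reference volumes must be positive")
        p_vals, locs = [], []
        for prof, mv in zip(profiles, y):
            amax, loc = find_acsa_max(prof)
            p_vals.append(shape_factor(mv, prof.length_mm, amax))
            locs.append(loc)
        self.p_ = np.asarray(p_vals)
        self.locations_ = np.asarray(locs)
        self.p_avg_ = float(self.p_.mean())
        self.p_sd_ = float(self.p_.std(ddof=1))
        self.acsa_max_location_ = float(self.locations_.mean())
        self.n_subjects_ = len(profiles)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "p_avg_"):
            raise NotFittedError("ShapeFactorVolume must be fitted before predicting")

    def _predict_one(self, prof: AcsaProfile, p_avg: float, loc: float) -> float:
        area = find_acsa_max(prof)[0] if self.ideal else acsa_at(prof, loc)
        return p_avg * prof.length_mm * area

    def predict(self, X) -> np.ndarray:
        """Estimated volumes, mm^3: p_avg * L * ACSA(average ACSA_max location)."""
        self._check_fitted()
        profiles = _as_profiles(X)
        return np.asarray(
            [self._predict_one(p, self.p_avg_, self.acsa_max_location_) for p in profiles]
        )

    def fit_predict(self, X, y) -> np.ndarray:
        """Fit and predict on the cohort, optionally leave-one-out."""
        self.fit(X, y)
        if not self.leave_one_out:
            return self.predict(X)
        profiles = _as_profiles(X)
        n = self.n_subjects_
        out = np.empty(n)
        for i, prof in enumerate(profiles):
            p_avg = (self.p_.sum() - self.p_[i]) / (n - 1)
            loc = (self.locations_.sum() - self.locations_[i]) / (n - 1)
            out[i] = self._predict_one(prof, p_avg, loc)
        return out


class TruncatedConeVolume(BaseEstimator):
    """Five-slice truncated-cone (frustum) muscle-volume estimator.

    Parameters
    ----------
    location : float or None, default None
        Anchor position of the central sampled slice (the ACSA_max location,
        fraction of muscle length).  If None it is learned in ``fit`` as the
        cohort mean of per-subject ACSA_max locations; if given, ``fit`` is
        optional.

    Attributes
    ----------
    acsa_max_location_ : float
        The anchor location actually used for the five-slice placement.
    sampling_ : TruncatedConeSampling
        The five relative positions.
    """

    def __init__(self, location: float | None = None):
        self.location = location

    def fit(self, X=None, y=None) -> "TruncatedConeVolume":
        """Learn the anchor location from the cohort (or adopt the fixed one)."""
        if self.location is not None:
            loc = float(self.location)
        else:
            profiles = _as_profiles(X)
            loc = float(np.mean([find_acsa_max(p)[1] for p in profiles]))
        self.acsa_max_location_ = loc
        self.sampling_ = truncated_cone_positions(loc)
        return self

    def predict(self, X) -> np.ndarray:
        """Estimated volumes, mm^3, from the four frustum segments."""
        if not hasattr(self, "sampling_"):
            if self.location is None:
                raise NotFittedError(
                    "TruncatedConeVolume needs fit() or an explicit location"
                )
            self.fit()
        return np.asarray(
            [estimate_truncated_cone(p, self.sampling_) for p in _as_profiles(X)]
        )

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)


# ---------------------------------------------------------------------------
# Thin functional wrappers over the estimator classes.

def fit_shape_factor_model(
    profiles, mv_ref_mm3, leave_one_out: bool = False
) -> ShapeFactorVolume:
    """Fit a :class:`ShapeFactorVolume` on a cohort (thin wrapper)."""
    return ShapeFactorVolume(leave_one_out=leave_one_out).fit(profiles, mv_ref_mm3)


def estimate_shape_factor(
    model: ShapeFactorVolume,
    profile: AcsaProfile,
    ideal: bool | None = None,
    p: float | None = None,
) -> float:
    """Shape-factor volume estimate for one profile.

    ``ideal`` overrides the model's mode (sample the subject's own ACSA_max);
    ``p`` substitutes a subject-specific shape factor for the cohort mean.
    With both (own p, own ACSA_max) the estimate inverts the shape-factor
    definition and reproduces the subject's reference volume exactly.
    """
    model._check_fitted()
    use_ideal = model.ideal if ideal is None else ideal
    p_use = model.p_avg_ if p is None else p
    area = (
        find_acsa_max(profile)[0]
        if use_ideal
        else acsa_at(profile, model.acsa_max_location_)
    )
    return p_use * profile.length_mm * area
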