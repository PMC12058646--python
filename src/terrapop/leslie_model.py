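"""Female-only, five-class projection matrix for a long-lived estuarine turtle.

Age classes are 0, 1, 2, 3 and a pooled reproductive class 4+ (age at first
breeding m = 4, longevity l = 40).  The matrix is

        [ 0    0    0    0    F   ]
        [ S_j  0    0    0    0   ]
    A = [ 0    S_j  0    0    0   ]
        [ 0    0    S_sa 0    0   ]
        [ 0    0    0    S_sa P_a ]

with fertility F = (clutch size x clutches per season x clutch survival x
egg survival x proportion female) x S_j^(9/12) — female hatchlings per
breeding female discounted by juvenile survival over the nine months from
hatching to the next annual census — and the 4+ retention probability P_a
given by the fixed-stage-duration approximation

    P_a = S_a (1 - (S_a/lambda)^(T-1)) / (1 - (S_a/lambda)^T),  T = l - m + 1

(Caswell's gamma-corrected stage survival, with the reference lambda fixed
at 1).  Subadult survival S_sa equals adult survival S_a.  The dominant
eigenvalue of A is the asymptotic growth rate and its right eigenvector the
stable age distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace

import numpy as np
import scipy.linalg
import scipy.optimize

__all__ = [
    "VitalRates",
    "ProjectionMatrix",
    "EigenReport",
    "hatchlings_per_female",
    "fertility",
    "stage_retention",
    "build_matrix",
    "eigen_analysis",
    "solve_Sj",
]

CLASS_LABELS = ("age0", "age1", "age2", "age3", "age4plus")


class LeslieError(ValueError):
    pass


@dataclass(frozen=True)
class VitalRates:
    """Vital rates parameterizing the projection matrix.

    Defaults are the study population's literature values: Florida clutch
    size and clutch frequency, northern-population clutch/egg survival, a
    1:1 hatchling sex ratio, juvenile survival calibrated so that projected
    growth matches mark-recapture realized growth (lambda = 1.034 gives
    S_j = 0.565), maturity at 4 years and 40-year longevity.  ``S_a`` is
    the year-specific adult annual survival supplied by the user (typically
    a CJS estimate) and has no meaningful global default.
    """

    clutch_size: float = 6.7
    clutches_per_season: float = 2.5
    clutch_survival: float = 0.097
    egg_survival: float = 0.8735
    prop_female: float = 0.5
    S_j: float = 0.565
    S_a: float = 0.9
    longevity_l: int = 40
    maturity_m: int = 4
    lambda_ref: float = 1.0

    def __post_init__(self) -> None:
        for name in ("clutch_survival", "egg_survival", "prop_female", "S_j", "S_a"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise LeslieError(f"{name} must be in [0, 1], got {v}")
        if not self.longevity_l >= self.maturity_m >= 1:
            raise LeslieError(
                f"need longevity >= maturity >= 1, got l={self.longevity_l}, "
                f"m={self.maturity_m}"
            )
        if self.lambda_ref <= 0:
            raise LeslieError("lambda_ref must be positive")

    @property
    def stage_duration(self) -> int:
        """T = l - m + 1, the duration of the pooled 4+ stage."""
        return self.longevity_l - self.maturity_m + 1

    def with_Sa(self, S_a: float) -> "VitalRates":
        return replace(self, S_a=S_a)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "VitalRates":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "VitalRates":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ProjectionMatrix:
    A: np.ndarray
    class_labels: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self) -> None:
        a = np.asarray(self.A, dtype=float)
        if a.shape != (5, 5):
            raise LeslieError(f"projection matrix must be 5x5, got {a.shape}")
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise LeslieError("matrix entries must be finite and nonnegative")
        pattern = {(0, 4), (1, 0), (2, 1), (3, 2), (4, 3), (4, 4)}
        nz = set(zip(*np.nonzero(a)))
        if not nz <= pattern:
            raise LeslieError(f"unexpected nonzero entries at {sorted(nz - pattern)}")
        surv = a[[1, 2, 3, 4, 4], [0, 1, 2, 3, 4]]
        if np.any(surv > 1.0 + 1e-12):
            raise LeslieError("survival entries must be <= 1")
        object.__setattr__(self, "A", a)


@dataclass(frozen=True)
class EigenReport:
    lambda_dom: float
    stable_age: np.ndarray
    primitive: bool = True


def hatchlings_per_female(v: VitalRates) -> float:
    """Female hatchlings per breeding female per season.

    The product clutch_size x clutches_per_season x clutch_survival x
    egg_survival x prop_female (0.7096 at the defaults).
    """
    return (
        v.clutch_size
        * v.clutches_per_season
        * v.clutch_survival
        * v.egg_survival
        * v.prop_female
    )


def fertility(v: VitalRates) -> float:
    """Fertility F: female hatchlings per female surviving to the next census.

    Hatchlings emerge ~3 months into the annual cycle, so the hatchling
    count is discounted by juvenile survival over the remaining 9 months:
    F = hatchlings_per_female x S_j^(9/12).
    """
    return hatchlings_per_female(v) * v.S_j ** (9.0 / 12.0)


def stage_retention(
    S_a: float, maturity_m: int = 4, longevity_l: int = 40, lambda_ref: float = 1.0
) -> float:
    """Probability of surviving and remaining in the pooled terminal stage.

    Fixed-stage-duration approximation with stage duration T = l - m + 1:

        P_a = S_a (1 - (S_a/lambda)^(T-1)) / (1 - (S_a/lambda)^T)

    with the analytic limit S_a (T-1)/T at S_a = lambda.  Limits: T = 1
    gives 0 (everyone exits a one-year stage); T -> inf with S_a < lambda
    gives S_a.
    """
    if not 0.0 <= S_a <= 1.0:
        raise LeslieError(f"S_a must be in [0, 1], got {S_a}")
    T = longevity_l - maturity_m + 1
    if T < 1:
        raise LeslieError(f"stage duration T = {T} < 1")
    if T == 1 or S_a == 0.0:
        return 0.0
    r = S_a / lambda_ref
    if abs(r - 1.0) < 1e-12:
        return S_a * (T - 1) / T
    return S_a * (1.0 - r ** (T - 1)) / (1.0 - r**T)


def build_matrix(v: VitalRates) -> ProjectionMatrix:
    """Assemble the 5x5 projection matrix from vital rates.

    Juvenile survival S_j sits on the 0->1 and 1->2 transitions and
    subadult survival (= S_a) on 2->3 and 3->4+, following the operational
    matrix used for simulation.  Set ``sj_through_age2=True`` via
    :func:`build_matrix_variant` for the alternative reading that keeps
    S_j on the 2->3 transition.
    """
    return build_matrix_variant(v, sj_through_age2=False)


def build_matrix_variant(v: VitalRates, sj_through_age2: bool = False) -> ProjectionMatrix:
    F = fertility(v)
    P_a = stage_retention(v.S_a, v.maturity_m, v.longevity_l, v.lambda_ref)
    S_sa = v.S_a
    a = np.zeros((5, 5))
    a[0, 4] = F
    a[1, 0] = v.S_j
    a[2, 1] = v.S_j
    a[3, 2] = v.S_j if sj_through_age2 else S_sa
    a[4, 3] = S_sa
    a[4, 4] = P_a
    return ProjectionMatrix(a)


def eigen_analysis(pm: ProjectionMatrix | np.ndarray) -> EigenReport:
    """Dominant eigenvalue and stable age distribution of the matrix.

    The sparsity pattern with positive fertility and subdiagonals is
    primitive, so the dominant eigenvalue is real and simple
    (Perron-Frobenius); the right eigenvector, normalized to sum to one, is
    the stable age distribution.  For degenerate matrices (zero fertility
    or a broken subdiagonal) the computed values are still returned with
    ``primitive=False``.
    """
    a = pm.A if isinstance(pm, ProjectionMatrix) else np.asarray(pm, dtype=float)
    vals, vecs = scipy.linalg.eig(a)
    i = int(np.argmax(np.abs(vals)))
    lam = vals[i]
    w = vecs[:, i]
    n = a.shape[0]
    subdiag = a[np.arange(1, n), np.arange(n - 1)]
    primitive = bool(a[0, -1] > 0 and np.all(subdiag > 0))
    lam_dom = float(np.real(lam))
    w = np.real(w)
    s = w.sum()
    if s != 0:
        w = w / s
    w = np.where(np.abs(w) < 1e-14, 0.0, w)
    return EigenReport(lambda_dom=lam_dom, stable_age=w, primitive=primitive)


def solve_Sj(
    target_lambda: float,
    v: VitalRates,
    tol: float = 1e-10,
    eps: float = 1e-6,
) -> float:
    """Solve for the juvenile survival that makes projected growth hit a target.

    Finds S_j in (0, 1) such that the dominant eigenvalue of A(S_j) equals
    ``target_lambda``, by bracketing bisection (Brent).  Fertility depends
    on S_j through the nine-month discount, so the solve includes that
    coupling.  The growth rate is strictly increasing in S_j for this
    matrix family, so the root is unique when it exists.
    """

    def g(sj: float) -> float:
        return eigen_analysis(build_matrix(replace(v, S_j=sj))).lambda_dom - target_lambda

    lo, hi = eps, 1.0 - eps
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        lam_lo = glo + target_lambda
        lam_hi = ghi + target_lambda
        raise LeslieError(
            f"target lambda {target_lambda} outside achievable range "
            f"[{lam_lo:.6f}, {lam_hi:.6f}] for S_j in ({eps}, {1 - eps})"
        )
    return float(scipy.optimize.brentq(g, lo, hi, xtol=tol))
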