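"""Gamma-parameterized uncertainty propagation through a polynomial chaos expansion.

Each uncertain HGO coefficient is given a gamma distribution moment-matched to
its literature mean and a standard deviation expressed as a percentage of that
mean (shape k_g = (mu/sigma)^2, scale theta = sigma^2/mu).  A total-degree
order-4 PCE in the five parameters (c, k1, k2, gamma, kappa) is fitted by
least squares on a Monte-Carlo design of P + oversample points, where
P = C(5+4, 4) = 126 and the default oversample of 10 gives the 136-run design.
The basis is the product of generalized-Laguerre polynomials orthonormal under
each parameter's own gamma measure, so first- and total-order Sobol indices
follow directly from the squared coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "GammaSpec",
    "PolynomialChaosExpansion",
    "PCEResults",
    "SobolResult",
    "std_pct_from_layer_stats",
    "gamma_from_mean_stdpct",
    "multi_indices",
    "n_total_degree_basis",
    "MEDIA_LAYER_STATS",
    "PRINTED_STD_PCT",
    "PRINTED_ROW_AVERAGE",
    "default_parameter_specs",
    "HGO_PARAMETER_NAMES",
]

HGO_PARAMETER_NAMES = ("c", "k1", "k2", "gamma", "kappa")

#: Adult-artery media-layer (mean, std) per parameter, used to derive the
#: std-as-percentage-of-mean magnitudes applied to the RVOT baselines.  The
#: trailing "epsilon" column belongs to the source's own constitutive model
#: and has no HGO counterpart; its printed percentage (48.89) is carried
#: verbatim for the row average and never recomputed.
MEDIA_LAYER_STATS = {
    "c": (1.27, 0.63),
    "k1": (21.6, 7.12),
    "k2": (8.21, 3.27),
    "gamma": (20.61, 5.5),
    "kappa": (0.25, 0.09),
    "epsilon": (0.05, 0.02),
}

PRINTED_STD_PCT = {
    "c": 49.61, "k1": 32.96, "k2": 39.83, "gamma": 26.69, "kappa": 36.0,
    "epsilon": 48.89,
}
PRINTED_ROW_AVERAGE = 39.0

#: RVOT baseline means (Young's-modulus-like in kPa, angle in deg, rest unitless)
BASELINE_MEANS = {"c": 200.0, "k1": 13480.0, "k2": 1.06, "gamma": 18.85, "kappa": 0.33}


def std_pct_from_layer_stats(mean: float, std: float) -> float:
    """Standard deviation as a percentage of the mean, rounded to 2 decimals."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    return round(100.0 * std / mean, 2)


@dataclass(frozen=True)
class GammaSpec:
    """Moment-matched gamma distribution for one uncertain parameter.

    mean = shape * scale and variance = shape * scale^2 hold by construction.
    """

    mean: float
    std_pct: float

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError(f"mean must be positive, got {self.mean}")
        if self.std_pct <= 0:
            raise ValueError(f"std percentage must be positive, got {self.std_pct}")

    @property
    def std(self) -> float:
        return self.mean * self.std_pct / 100.0

    @property
    def shape(self) -> float:
        return (self.mean / self.std) ** 2

    @property
    def scale(self) -> float:
        return self.std**2 / self.mean

    def frozen(self):
        return stats.gamma(a=self.shape, scale=self.scale)

    def rvs(self, size, rng: np.random.Generator) -> np.ndarray:
        return stats.gamma.rvs(a=self.shape, scale=self.scale, size=size, random_state=rng)


def gamma_from_mean_stdpct(mean: float, std_pct: float) -> GammaSpec:
    """Gamma spec from a mean and a std-as-percentage-of-mean."""
    return GammaSpec(mean=mean, std_pct=std_pct)


def default_parameter_specs() -> dict[str, GammaSpec]:
    """The five HGO gamma specs: baseline means with media-layer std percentages."""
    return {
        name: GammaSpec(BASELINE_MEANS[name], PRINTED_STD_PCT[name])
        for name in HGO_PARAMETER_NAMES
    }


# ---------------------------------------------------------------------------
# Orthonormal generalized-Laguerre basis
# ---------------------------------------------------------------------------

def _laguerre_orthonormal(n: int, alpha: float, t: np.ndarray) -> np.ndarray:
    """Generalized Laguerre polynomial orthonormal under Gamma(alpha+1, 1).

    ``int phi_m phi_n t^alpha e^-t / Gamma(alpha+1) dt = delta_mn``.
    """
    norm2 = math.exp(
        special.gammaln(n + alpha + 1) - special.gammaln(n + 1) - special.gammaln(alpha + 1)
    )
    return special.eval_genlaguerre(n, alpha, t) / math.sqrt(norm2)


def basis_1d(spec: GammaSpec, n: int, x: np.ndarray) -> np.ndarray:
    """Orthonormal polynomial of degree n under ``spec``'s gamma measure."""
    return _laguerre_orthonormal(n, spec.shape - 1.0, np.asarray(x, dtype=float) / spec.scale)


def gauss_rule(spec: GammaSpec, n_quad: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss nodes/weights for expectation under ``spec``'s gamma measure."""
    alpha = spec.shape - 1.0
    t, w = special.roots_genlaguerre(n_quad, alpha)
    return t * spec.scale, w / math.exp(special.gammaln(alpha + 1.0))


def multi_indices(dim: int, order: int) -> np.ndarray:
    """All multi-indices with total degree <= order, graded-lexicographic."""
    idx = [m for m in product(range(order + 1), repeat=dim) if sum(m) <= order]
    idx.sort(key=lambda m: (sum(m), m))
    return np.array(idx, dtype=int)


def n_total_degree_basis(dim: int, order: int) -> int:
    return math.comb(dim + order, order)


# ---------------------------------------------------------------------------
# PCE model
# ---------------------------------------------------------------------------

@dataclass
class PolynomialChaosExpansion:
    """Total-degree PCE over independent gamma-distributed parameters.

    Parameters
    ----------
    specs : dict
        Parameter name -> :class:`GammaSpec`, in sampling order.
    order : int
        Total polynomial degree (4 reproduces the 136-run study design).
    bounds : dict
        Optional per-parameter upper bounds enforced at sampling time
        (default: kappa <= 1/3, the admissible dispersion range).
    bound_mode : str
        "reject" redraws out-of-bound samples; "clip" truncates them
        (exposed for sensitivity of the enforcement choice).
    """

    specs: dict
    order: int = 4
    bounds: dict = field(default_factory=lambda: {"kappa": 1.0 / 3.0})
    bound_mode: str = "reject"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.bound_mode not in ("reject", "clip"):
            raise ValueError(f"unknown bound mode {self.bound_mode!r}")
        self.names = tuple(self.specs.keys())
        self.indices = multi_indices(len(self.names), self.order)

    @property
    def n_basis(self) -> int:
        return len(self.indices)

    # -- sampling ------------------------------------------------------------

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n independent draws from the product gamma measure (physical units)."""
        cols = []
        for name in self.names:
            spec = self.specs[name]
            x = spec.rvs(n, rng)
            hi = self.bounds.get(name)
            if hi is not None:
                if self.bound_mode == "clip":
                    x = np.minimum(x, hi)
                else:
                    bad = x > hi
                    while bad.any():
                        x[bad] = spec.rvs(int(bad.sum()), rng)
                        bad = x > hi
            cols.append(x)
        return np.column_stack(cols)

    def design(self, oversample: int = 10, rng: np.random.Generator | None = None,
               seed: int | None = None) -> np.ndarray:
        """Training design of ``n_basis + oversample`` Monte-Carlo points.

        Order 4 with five parameters and the default oversample of 10 yields
        the pinned 126 + 10 = 136 rows.
        """
        if oversample < 0:
            raise ValueError("oversample must be >= 0")
        if rng is None:
            rng = np.random.default_rng(seed)
        return self.sample(self.n_basis + oversample, rng)

    # -- basis and fit ---------------------------------------------------------

    def basis_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        # per-dimension univariate polynomial tables up to the max degree
        tables = []
        for d, name in enumerate(self.names):
            spec = self.specs[name]
            deg_max = int(self.indices[:, d].max())
            tables.append(
                np.stack([basis_1d(spec, n, X[:, d]) for n in range(deg_max + 1)], axis=0)
            )
        Phi = np.ones((X.shape[0], self.n_basis))
        for k, midx in enumerate(self.indices):
            for d, n in enumerate(midx):
                if n:
                    Phi[:, k] *= tables[d][n]
        return Phi

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PCEResults":
        """Least-squares fit; rows with non-finite outputs are dropped.

        Mirrors the study's failed-run policy: runs that did not complete are
        marked missing and the emulator is fitted on the survivors.  Raises if
        fewer survivors than basis functions remain.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).reshape(-1)
        ok = np.isfinite(y)
        n_used = int(ok.sum())
        if n_used < self.n_basis:
            raise ValueError(
                f"under-determined PCE fit: {n_used} usable runs < {self.n_basis} basis functions"
            )
        Phi = self.basis_matrix(X[ok])
        coef, _, rank, sv = np.linalg.lstsq(Phi, y[ok], rcond=None)
        cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else math.inf
        return PCEResults(model=self, coefficients=coef, n_used=n_used,
                          n_dropped=int(len(y) - n_used), condition_number=cond)


@dataclass(frozen=True)
class SobolResult:
    """First- and total-order Sobol indices per parameter, plus model variance."""

    parameters: tuple
    first_order: np.ndarray
    total_order: np.ndarray
    variance: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.parameters,
            "S_first": self.first_order,
            "S_total": self.total_order,
        })


@dataclass(frozen=True)
class PCEResults:
    """Fitted PCE emulator: coefficients, diagnostics, Sobol indices, sampling."""

    model: PolynomialChaosExpansion
    coefficients: np.ndarray
    n_used: int
    n_dropped: int
    condition_number: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.basis_matrix(X) @ self.coefficients

    @property
    def mean(self) -> float:
        return float(self.coefficients[0])

    @property
    def variance(self) -> float:
        return float(np.sum(self.coefficients[1:] ** 2))

    def partial_variances(self) -> dict[tuple, float]:
        """Variance per non-empty interaction subset (the ANOVA ledger)."""
        out: dict[tuple, float] = {}
        for k, midx in enumerate(self.model.indices):
            subset = tuple(d for d, n in enumerate(midx) if n > 0)
            if subset:
                out[subset] = out.get(subset, 0.0) + float(self.coefficients[k] ** 2)
        return out

    def sobol(self) -> SobolResult:
        """First- and total-order indices from the orthonormal coefficients."""
        idx = self.model.indices
        a2 = self.coefficients**2
        var = self.variance
        dim = idx.shape[1]
        first = np.zeros(dim)
        total = np.zeros(dim)
        if var > 0:
            for d in range(dim):
                own = (idx[:, d] > 0) & (np.delete(idx, d, axis=1).sum(axis=1) == 0)
                any_d = idx[:, d] > 0
                first[d] = a2[own].sum() / var
                total[d] = a2[any_d].sum() / var
        return SobolResult(parameters=self.model.names, first_order=first,
                           total_order=total, variance=var)

    def sample_summary(self, n: int = 1000, rng: np.random.Generator | None = None,
                       seed: int | None = None) -> dict:
        """Distribution summary of n emulator queries under the input measure."""
        if rng is None:
            rng = np.random.default_rng(seed)
        X = self.model.sample(n, rng)
        y = self.predict(X)
        return {
            "n": n,
            "min": float(np.min(y)),
            "q25": float(np.quantile(y, 0.25)),
            "median": float(np.median(y)),
            "q75": float(np.quantile(y, 0.75)),
            "max": float(np.max(y)),
            "samples": y,
        }

    def summary(self) -> str:
        """Human-readable fit report."""
        sob = self.sobol()
        lines = [
            "Polynomial chaos expansion (order "
            f"{self.model.order}, {self.model.n_basis} basis functions)",
            f"  training runs used: {self.n_used} (dropped {self.n_dropped})",
            f"  design condition number: {self.condition_number:.3g}",
            f"  emulator mean: {self.mean:.6g}   variance: {self.variance:.6g}",
            "  parameter   S_first   S_total",
        ]
        for name, s1, st in zip(sob.parameters, sob.first_order, sob.total_order):
            lines.append(f"  {name:<10s} {s1:8.4f}  {st:8.4f}")
        return "\n".join(lines)
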