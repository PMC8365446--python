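"""Saturation kinetics of ribonucleotide reductases.

Turnover arithmetic and nonlinear least-squares fitting of the
Michaelis–Menten model

    v = kcat * S / (KM + S)

and its uncompetitive substrate-surplus-inhibition extension

    v = kcat * S / (KM + S * (1 + S / Ki)),

which reduces to plain Michaelis–Menten as Ki → ∞.  Rates are turnover
numbers in min⁻¹ (product per enzyme per minute) and concentrations in
mmol L⁻¹.  Fitting uses unweighted Levenberg–Marquardt least squares
with standard errors from the Jacobian at the optimum; failure to
converge is reported as a flag on the fit, never raised.

The "apparent" fit refits plain Michaelis–Menten on a truncated
low-substrate subset where inhibition is not yet expressed; the
resulting KM is a lower bound on the true KM.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "RateDataset",
    "KineticModelFit",
    "activity_from_product",
    "mm_rate",
    "si_rate",
    "fit_model",
    "apparent_fit",
    "competition_ratio",
    "SaturationKinetics",
]

MODELS = ("MM", "MM_SI")


@dataclass(frozen=True)
class RateDataset:
    """A saturation-kinetics dataset: (substrate, rate) observations.

    ``substrate_mM`` in mmol L⁻¹, ``rate_per_min`` as turnover in min⁻¹,
    with an optional replicate id per point.
    """

    substrate_mM: tuple
    rate_per_min: tuple
    replicate: tuple | None = None
    enzyme_conc_uM: float | None = None
    substrate_name: str = ""
    effector_name: str = ""

    def __post_init__(self):
        s = tuple(float(x) for x in self.substrate_mM)
        v = tuple(float(x) for x in self.rate_per_min)
        if len(s) != len(v) or not s:
            raise ValueError("substrate and rate vectors must be equal, non-empty")
        if any(x <= 0 for x in s):
            raise ValueError("substrate concentrations must be > 0")
        if any(x < 0 for x in v):
            raise ValueError("rates must be >= 0")
        object.__setattr__(self, "substrate_mM", s)
        object.__setattr__(self, "rate_per_min", v)
        if self.replicate is not None and len(self.replicate) != len(s):
            raise ValueError("replicate ids must match data length")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "RateDataset":
        rep = tuple(df["replicate"]) if "replicate" in df else None
        return cls(substrate_mM=tuple(df["substrate_mM"]),
                   rate_per_min=tuple(df["rate_per_min"]),
                   replicate=rep, **kw)

    def to_frame(self) -> pd.DataFrame:
        d = {"substrate_mM": self.substrate_mM,
             "rate_per_min": self.rate_per_min}
        if self.replicate is not None:
            d["replicate"] = self.replicate
        return pd.DataFrame(d)

    def truncated(self, s_max: float) -> "RateDataset":
        keep = [i for i, s in enumerate(self.substrate_mM) if s <= s_max]
        if not keep:
            raise ValueError(f"no points at substrate <= {s_max}")
        return replace(
            self,
            substrate_mM=tuple(self.substrate_mM[i] for i in keep),
            rate_per_min=tuple(self.rate_per_min[i] for i in keep),
            replicate=(tuple(self.replicate[i] for i in keep)
                       if self.replicate is not None else None),
        )


def activity_from_product(product_uM: float, enzyme_uM: float,
                          time_min: float) -> float:
    """Turnover rate (min⁻¹) from product formed over a fixed time.

    ``rate = product / (enzyme * time)`` with product and enzyme in the
    same concentration unit (µmol L⁻¹).
    """
    if enzyme_uM <= 0 or time_min <= 0:
        raise ValueError("enzyme concentration and time must be > 0")
    if product_uM < 0:
        raise ValueError("product concentration must be >= 0")
    return product_uM / (enzyme_uM * time_min)


def mm_rate(S, kcat: float, km: float):
    """Michaelis–Menten turnover v = kcat·S/(KM + S), min⁻¹."""
    S = np.asarray(S, dtype=float)
    return kcat * S / (km + S)


def si_rate(S, kcat: float, km: float, ki: float):
    """Uncompetitive substrate-surplus inhibition:
    v = kcat·S/(KM + S·(1 + S/Ki)).  Maximal at S = sqrt(KM·Ki)."""
    S = np.asarray(S, dtype=float)
    return kcat * S / (km + S * (1.0 + S / ki))


@dataclass(frozen=True)
class KineticModelFit:
    """Fitted saturation-kinetics parameters with uncertainty.

    ``converged`` is False when the optimizer stalled or the estimates
    are not interpretable (non-positive parameters, singular Jacobian);
    the best parameter values found are still reported for diagnosis.
    """

    model: str
    kcat: float
    km: float
    ki: float | None
    kcat_se: float
    km_se: float
    ki_se: float | None
    converged: bool
    rss: float
    n_obs: int
    apparent: bool = False

    def predict(self, S):
        if self.model == "MM":
            return mm_rate(S, self.kcat, self.km)
        return si_rate(S, self.kcat, self.km, self.ki)

    def as_dict(self) -> dict:
        return {
            "model": self.model, "apparent": self.apparent,
            "kcat_per_min": self.kcat, "kcat_se": self.kcat_se,
            "km_mM": self.km, "km_se": self.km_se,
            "ki_mM": self.ki, "ki_se": self.ki_se,
            "converged": self.converged, "rss": self.rss, "n_obs": self.n_obs,
        }


def _initial_guess(S: np.ndarray, v: np.ndarray, model: str) -> np.ndarray:
    kcat0 = float(v.max()) if v.max() > 0 else 1.0
    half = kcat0 / 2.0
    # substrate closest to half-maximal rate; scale-free and robust
    km0 = float(S[np.argmin(np.abs(v - half))])
    km0 = max(km0, 1e-6)
    if model == "MM":
        return np.array([kcat0, km0])
    return np.array([kcat0, km0, float(S.max())])


class SaturationKinetics(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares estimator for saturation kinetics.

    Parameters
    ----------
    model : {"mm", "mm_si"}
        Plain Michaelis–Menten or the substrate-surplus-inhibition form.
    xtol : float
        Relative step tolerance of the Levenberg–Marquardt optimizer.
    max_iter : int
        Cap on function evaluations.

    Attributes (after :meth:`fit`)
    ------------------------------
    kcat_, km_, ki_ : point estimates (ki_ is None for plain MM)
    kcat_se_, km_se_, ki_se_ : standard errors from the Jacobian
    converged_ : bool
    rss_ : residual sum of squares
    """

    def __init__(self, model: str = "mm", xtol: float = 1e-8,
                 max_iter: int = 500):
        self.model = model
        self.xtol = xtol
        self.max_iter = max_iter

    def _canonical_model(self) -> str:
        m = str(self.model).upper()
        if m not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        return m

    def fit(self, X, y=None):
        """Fit to substrate concentrations ``X`` (mM) and rates ``y`` (min⁻¹)."""
        model = self._canonical_model()
        S = np.asarray(X, dtype=float).ravel()
        v = np.asarray(y, dtype=float).ravel()
        if S.shape != v.shape:
            raise ValueError("X and y must have the same length")
        n_distinct = np.unique(S).size
        need = 4 if model == "MM" else 5
        if n_distinct < need:
            raise ValueError(
                f"{model} fit needs >= {need} distinct substrate "
                f"concentrations, got {n_distinct}")

        def resid(theta):
            if model == "MM":
                return mm_rate(S, theta[0], theta[1]) - v
            return si_rate(S, theta[0], theta[1], theta[2]) - v

        theta0 = _initial_guess(S, v, model)
        res = least_squares(resid, theta0, method="lm",
                            xtol=self.xtol, ftol=self.xtol, gtol=self.xtol,
                            max_nfev=self.max_iter)
        theta = res.x
        rss = float(2.0 * res.cost)
        n, p = S.size, theta.size

        se = np.full(p, np.inf)
        jac_ok = False
        try:
            jtj = res.jac.T @ res.jac
            cov = np.linalg.inv(jtj)
            sigma2 = rss / max(n - p, 1)
            diag = np.diag(cov) * sigma2
            if np.all(np.isfinite(diag)) and np.all(diag >= 0):
                se = np.sqrt(diag)
                jac_ok = True
        except np.linalg.LinAlgError:
            pass

        converged = bool(res.success) and jac_ok and bool(np.all(theta > 0))

        self.n_obs_ = int(n)
        self.kcat_, self.km_ = float(theta[0]), float(theta[1])
        self.kcat_se_, self.km_se_ = float(se[0]), float(se[1])
        if model == "MM_SI":
            self.ki_, self.ki_se_ = float(theta[2]), float(se[2])
        else:
            self.ki_, self.ki_se_ = None, None
        self.converged_ = converged
        self.rss_ = rss
        return self

    def predict(self, X):
        S = np.asarray(X, dtype=float).ravel()
        if self._canonical_model() == "MM":
            return mm_rate(S, self.kcat_, self.km_)
        return si_rate(S, self.kcat_, self.km_, self.ki_)

    def result_(self, apparent: bool = False) -> KineticModelFit:
        return KineticModelFit(
            model=self._canonical_model(),
            kcat=self.kcat_, km=self.km_, ki=self.ki_,
            kcat_se=self.kcat_se_, km_se=self.km_se_, ki_se=self.ki_se_,
            converged=self.converged_, rss=self.rss_, n_obs=self.n_obs_,
            apparent=apparent)


def fit_model(data: RateDataset, model: str = "mm",
              xtol: float = 1e-8, max_iter: int = 500) -> KineticModelFit:
    """Fit a saturation-kinetics model to a :class:`RateDataset`."""
    est = SaturationKinetics(model=model, xtol=xtol, max_iter=max_iter)
    est.fit(np.asarray(data.substrate_mM), np.asarray(data.rate_per_min))
    return est.result_()


def apparent_fit(data: RateDataset, s_max: float,
                 xtol: float = 1e-8, max_iter: int = 500) -> KineticModelFit:
    """Plain Michaelis–Menten fit on the subset with substrate <= s_max.

    Used when substrate inhibition distorts the full curve: fitting only
    the low-substrate range where inhibition is not yet expressed yields
    *apparent* parameters, and the apparent KM can only serve as a lower
    bound on the true KM.
    """
    sub = data.truncated(s_max)
    if np.unique(sub.substrate_mM).size < 4:
        raise ValueError("truncation leaves fewer than 4 distinct "
                         "substrate concentrations")
    est = SaturationKinetics(model="mm", xtol=xtol, max_iter=max_iter)
    est.fit(np.asarray(sub.substrate_mM), np.asarray(sub.rate_per_min))
    return est.result_(apparent=True)


def competition_ratio(products: Mapping[str, float],
                      numerator: str | None = None,
                      reference: str | None = None) -> float:
    """Fold ratio of two product concentrations from a competition assay.

    By default the largest product over the smallest; pass ``numerator``
    and ``reference`` species names to fix the direction (e.g.
    dGDP over dGTP).
    """
    if len(products) < 2:
        raise ValueError("need at least two product species")
    if numerator is None or reference is None:
        items = sorted(products.items(), key=lambda kv: kv[1])
        reference = reference or items[0][0]
        numerator = numerator or items[-1][0]
    ref = float(products[reference])
    if ref <= 0:
        raise ValueError(f"reference species {reference!r} concentration "
                         "must be > 0")
    return float(products[numerator]) / ref
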