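"""Least-squares estimation of lethality, HRF and RSF from survival curves.

The three estimators mirror the staged fitting protocol used with this model:

1. :class:`LethalityFit` — fit (k_idsb, k_cdsb) to the normoxic, untreated
   curve of a cell line.
2. :class:`HrfFit` — with the lethalities frozen, fit the hypoxia reduction
   factor to a hypoxic curve.
3. :class:`RsfFit` — with the lethalities frozen, fit the radiosensitization
   factor to a repair-impaired normoxic curve.

The combined hypoxia + repair-impairment survival is then a zero-free-
parameter prediction (:func:`predict_combined`), because HRF and RSF act on
disjoint model components and are each invariant under the other condition.

All estimators follow the scikit-learn API: ``X`` is the dose column (shape
``(n, 1)`` or ``(n,)``, Gy), ``y`` the surviving fraction in (0, 1]. The
objective is unweighted least squares on ln(surviving fraction), which
weights the decades of a survival curve comparably; pass ``sample_weight``
(1/sigma^2 in log space) to weight by measurement uncertainty. Zero-dose
records carry no information after plating-efficiency normalization and are
dropped. Fits use the deterministic closed-form evaluator, so results are
reproducible bit-for-bit for identical inputs and solver settings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .conditions import OxygenCondition, RepairImpairment, condition_adjusted_params
from .data import SurvivalDataset
from .model import (
    ModelParameters,
    analytic_mean_survival,
    loop_count,
)

__all__ = [
    "FitResult",
    "LethalityFit",
    "HrfFit",
    "RsfFit",
    "fit_lethality",
    "fit_hrf",
    "fit_rsf",
    "predict_combined",
    "lq_taylor_coefficients",
]

K_BOUNDS = (1e-6, 1.0)
HRF_BOUNDS = (1.0, 10.0)
_BOUNDARY_RTOL = 1e-6


@dataclass
class FitResult:
    """Point estimates, 1-sigma uncertainties and convergence metadata.

    ``std_errors`` are derived from the Jacobian-based covariance at the
    optimum (NaN when the residual degrees of freedom are zero).
    """

    estimates: dict[str, float]
    std_errors: dict[str, float]
    objective_value: float
    converged: bool
    n_points: int
    message: str = ""
    fixed: dict[str, float] = field(default_factory=dict)
    covariance: np.ndarray | None = None  # ordered as ``estimates``

    def __post_init__(self) -> None:
        for name, se in self.std_errors.items():
            if np.isfinite(se) and se < 0:
                raise ValueError(f"negative standard error for {name}")

    def interval(self, name: str, n_sigma: float = 1.0) -> tuple[float, float]:
        """Symmetric +/- n-sigma interval for one parameter."""
        est, se = self.estimates[name], self.std_errors[name]
        return est - n_sigma * se, est + n_sigma * se

    def summary(self) -> str:
        lines = [f"converged: {self.converged}  objective: {self.objective_value:.4g}  "
                 f"points: {self.n_points}"]
        for name, est in self.estimates.items():
            se = self.std_errors[name]
            lines.append(f"  {name} = {est:.6g} +/- {se:.3g}")
        for name, val in self.fixed.items():
            lines.append(f"  {name} = {val:.6g} (fixed)")
        return "\n".join(lines)


def _as_dose_column(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError(f"X must be a single dose column, got shape {X.shape}")
        X = X[:, 0]
    elif X.ndim != 1:
        raise ValueError(f"X must be 1-D or a column vector, got shape {X.shape}")
    if np.any(X < 0) or not np.all(np.isfinite(X)):
        raise ValueError("doses must be finite and non-negative")
    return X


class _SurvivalCurveFit(RegressorMixin, BaseEstimator):
    """Shared machinery: validation, multi-start bounded least squares on
    log-survival residuals, covariance-based uncertainties."""

    #: subclasses: ordered free-parameter names
    _free: tuple[str, ...] = ()
    #: minimum number of distinct nonzero doses required
    _min_doses = 3

    # -- model hooks -------------------------------------------------------
    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def _model_params(self, theta: np.ndarray) -> tuple[ModelParameters, float]:
        """Map the free-parameter vector to (ModelParameters, rsf)."""
        raise NotImplementedError

    def _fixed(self) -> dict[str, float]:
        return {}

    # -- fitting -----------------------------------------------------------
    def _log_model(self, theta: np.ndarray, dose: np.ndarray) -> np.ndarray:
        params, rsf = self._model_params(theta)
        return np.log(analytic_mean_survival(params, dose, rsf))

    def fit(self, X, y, sample_weight=None):
        """Fit the free parameters to (dose, surviving fraction) data."""
        dose = _as_dose_column(X)
        y = np.asarray(y, dtype=float)
        if y.shape != dose.shape:
            raise ValueError("X and y must have matching lengths")
        bad = np.where(~np.isfinite(y) | (y <= 0) | (y > 1))[0]
        if bad.size:
            raise ValueError(
                f"surviving fractions must lie in (0, 1]; offending record(s) at "
                f"index {bad.tolist()}"
            )
        keep = dose > 0  # zero-dose records are uninformative by normalization
        dose, y = dose[keep], y[keep]
        if sample_weight is not None:
            sample_weight = np.asarray(sample_weight, dtype=float)[keep]
            if np.any(sample_weight < 0):
                raise ValueError("sample_weight must be non-negative")
        if np.unique(dose).size < self._min_doses:
            raise ValueError(
                f"need at least {self._min_doses} distinct nonzero doses, "
                f"got {np.unique(dose).size}"
            )
        log_sf = np.log(y)
        sqrt_w = np.sqrt(sample_weight) if sample_weight is not None else None

        def residuals(theta):
            r = self._log_model(theta, dose) - log_sf
            return r * sqrt_w if sqrt_w is not None else r

        lo, hi = self._bounds()
        best = None
        for theta0 in self._starts(lo, hi):
            try:
                res = least_squares(
                    residuals, theta0, bounds=(lo, hi), method="trf",
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception as err:  # solver failure on one start is survivable
                warnings.warn(f"least-squares start failed: {err}")
                continue
            if best is None or res.cost < best.cost:
                best = res

        n = dose.size
        p = len(self._free)
        if best is None:
            self.fit_result_ = FitResult(
                estimates={name: np.nan for name in self._free},
                std_errors={name: np.nan for name in self._free},
                objective_value=np.nan, converged=False, n_points=n,
                message="all optimizer starts failed", fixed=self._fixed(),
            )
            return self

        cov = self._covariance(best, n, p)
        cov = self._augment_covariance(cov, best, dose, sqrt_w)
        std = [float(np.sqrt(max(cov[i, i], 0.0))) if cov is not None else float("nan")
               for i in range(p)]
        estimates = dict(zip(self._free, best.x.tolist()))
        self._warn_on_bounds(estimates, lo, hi)
        self.fit_result_ = FitResult(
            estimates=estimates,
            std_errors=dict(zip(self._free, std)),
            objective_value=float(2.0 * best.cost),  # sum of squared residuals
            converged=bool(best.success),
            n_points=int(n),
            message=str(best.message),
            fixed=self._fixed(),
            covariance=cov,
        )
        for name, value in estimates.items():
            setattr(self, f"{name}_", value)
            setattr(self, f"{name}_stderr_", self.fit_result_.std_errors[name])
        self.n_points_ = int(n)
        return self

    def _starts(self, lo: np.ndarray, hi: np.ndarray) -> list[np.ndarray]:
        """Multi-start initial points: geometric midpoint plus log-uniform draws."""
        mid = np.sqrt(np.maximum(lo, 1e-12) * hi)
        starts = [mid]
        n_extra = int(getattr(self, "n_starts", 1)) - 1
        if n_extra > 0:
            rng = np.random.default_rng(getattr(self, "random_state", 0))
            log_lo = np.log(np.maximum(lo, 1e-12))
            log_hi = np.log(hi)
            for _ in range(n_extra):
                starts.append(np.exp(rng.uniform(log_lo, log_hi)))
        return starts

    @staticmethod
    def _covariance(res, n: int, p: int) -> np.ndarray | None:
        """Jacobian-based covariance of the free parameters at the optimum."""
        if n <= p:
            return None
        ssr = 2.0 * res.cost
        s2 = ssr / (n - p)
        jtj = res.jac.T @ res.jac
        try:
            return np.linalg.inv(jtj) * s2
        except np.linalg.LinAlgError:
            return None

    def _augment_covariance(self, cov, res, dose, sqrt_w):
        """Hook for subclasses that condition on previously fitted parameters."""
        return cov

    def _warn_on_bounds(self, estimates: dict[str, float], lo, hi) -> None:
        for (name, value), l, h in zip(estimates.items(), lo, hi):
            span = h - l
            if value - l < _BOUNDARY_RTOL * span or h - value < _BOUNDARY_RTOL * span:
                warnings.warn(
                    f"estimate of {name} ({value:.4g}) is pinned at a bound "
                    f"[{l:.4g}, {h:.4g}]; treat it as a limit, not a measurement"
                )

    def predict(self, X) -> np.ndarray:
        """Predicted surviving fraction at the given doses."""
        if not hasattr(self, "fit_result_"):
            raise AttributeError("estimator is not fitted yet; call fit first")
        dose = _as_dose_column(X)
        theta = np.array([self.fit_result_.estimates[name] for name in self._free])
        return np.exp(self._log_model(theta, dose))


class LethalityFit(_SurvivalCurveFit):
    """Fit the lesion lethalities (k_idsb, k_cdsb) to a normoxic, untreated
    survival curve.

    Parameters
    ----------
    alpha_dsb, dna_content, loop_size : float
        Model constants (DSB/(Mbp*Gy), Mbp, Mbp).
    k_bounds : tuple
        Bounds applied to both lethality probabilities.
    n_starts : int
        Optimizer starts (log-uniform over the bounds) guarding against local
        minima of the two-parameter objective.
    random_state : int
        Seed for the start-point draws.

    Attributes
    ----------
    k_idsb_, k_cdsb_ : float
        Fitted lethality probabilities.
    k_idsb_stderr_, k_cdsb_stderr_ : float
        1-sigma uncertainties.
    fit_result_ : FitResult
    """

    _free = ("k_idsb", "k_cdsb")

    def __init__(
        self,
        alpha_dsb: float = 5e-3,
        dna_content: float = 6000.0,
        loop_size: float = 2.0,
        k_bounds: tuple[float, float] = K_BOUNDS,
        n_starts: int = 5,
        random_state: int = 0,
    ):
        self.alpha_dsb = alpha_dsb
        self.dna_content = dna_content
        self.loop_size = loop_size
        self.k_bounds = k_bounds
        self.n_starts = n_starts
        self.random_state = random_state

    def _bounds(self):
        lo, hi = self.k_bounds
        return np.array([lo, lo]), np.array([hi, hi])

    def _model_params(self, theta):
        params = ModelParameters(
            alpha_dsb=self.alpha_dsb, dna_content=self.dna_content,
            loop_size=self.loop_size, k_idsb=theta[0], k_cdsb=theta[1],
        )
        return params, 1.0

    def model_parameters_(self) -> ModelParameters:
        """Fitted :class:`ModelParameters` (after fit)."""
        return ModelParameters(
            alpha_dsb=self.alpha_dsb, dna_content=self.dna_content,
            loop_size=self.loop_size, k_idsb=self.k_idsb_, k_cdsb=self.k_cdsb_,
        )


class _FrozenLethalityFit(_SurvivalCurveFit):
    """Base for the single-factor fits with lethalities frozen.

    When ``k_cov`` (the 2x2 covariance of the frozen (k_idsb, k_cdsb)
    estimates from the lethality stage) is supplied, its uncertainty is
    propagated into the reported standard errors to first order — the staged
    protocol conditions on the stage-one estimates, and the purely
    conditional errors would otherwise understate the uncertainty of the
    factor (most severely for the RSF, which trades off directly against
    k_idsb through rsf * k_idsb).
    """

    def __init__(
        self,
        k_idsb: float,
        k_cdsb: float,
        alpha_dsb: float = 5e-3,
        dna_content: float = 6000.0,
        loop_size: float = 2.0,
        n_starts: int = 1,
        random_state: int = 0,
        k_cov=None,
    ):
        self.k_idsb = k_idsb
        self.k_cdsb = k_cdsb
        self.alpha_dsb = alpha_dsb
        self.dna_content = dna_content
        self.loop_size = loop_size
        self.n_starts = n_starts
        self.random_state = random_state
        self.k_cov = k_cov

    def _base_params(self, k_idsb: float | None = None,
                     k_cdsb: float | None = None) -> ModelParameters:
        return ModelParameters(
            alpha_dsb=self.alpha_dsb, dna_content=self.dna_content,
            loop_size=self.loop_size,
            k_idsb=self.k_idsb if k_idsb is None else k_idsb,
            k_cdsb=self.k_cdsb if k_cdsb is None else k_cdsb,
        )

    def _fixed(self):
        return {"k_idsb": self.k_idsb, "k_cdsb": self.k_cdsb}

    def _log_model_k(self, theta, dose, k_idsb, k_cdsb) -> np.ndarray:
        """Log-survival with explicit (possibly perturbed) frozen lethalities."""
        raise NotImplementedError

    def _augment_covariance(self, cov, res, dose, sqrt_w):
        if cov is None or self.k_cov is None:
            return cov
        k_cov = np.asarray(self.k_cov, dtype=float)
        theta = res.x
        # d(residual)/d(frozen k) by central differences at the optimum
        jk = np.empty((dose.size, 2))
        for j, (name, value) in enumerate((("k_idsb", self.k_idsb),
                                           ("k_cdsb", self.k_cdsb))):
            eps = max(abs(value), 1e-4) * 1e-6
            hi = self._log_model_k(theta, dose,
                                   self.k_idsb + (eps if j == 0 else 0.0),
                                   self.k_cdsb + (eps if j == 1 else 0.0))
            lo = self._log_model_k(theta, dose,
                                   self.k_idsb - (eps if j == 0 else 0.0),
                                   self.k_cdsb - (eps if j == 1 else 0.0))
            jk[:, j] = (hi - lo) / (2.0 * eps)
        if sqrt_w is not None:
            jk *= sqrt_w[:, None]
        jt = res.jac
        # implicit-function sensitivity of the optimum to the frozen k's:
        # d(theta_hat)/dk = -(Jt' Jt)^-1 Jt' Jk  (Gauss-Newton approximation)
        try:
            sens = -np.linalg.solve(jt.T @ jt, jt.T @ jk)
        except np.linalg.LinAlgError:
            return cov
        return cov + sens @ k_cov @ sens.T


class HrfFit(_FrozenLethalityFit):
    """Fit the hypoxia reduction factor to a hypoxic survival curve.

    The lethality parameters are frozen at their normoxic estimates; the
    single free parameter ``hrf`` in [1, 10] divides the DSB induction rate.

    Attributes
    ----------
    hrf_ : float
    hrf_stderr_ : float
    fit_result_ : FitResult
    """

    _free = ("hrf",)

    def __init__(self, k_idsb, k_cdsb, alpha_dsb=5e-3, dna_content=6000.0,
                 loop_size=2.0, hrf_bounds: tuple[float, float] = HRF_BOUNDS,
                 n_starts=1, random_state=0, k_cov=None):
        super().__init__(k_idsb, k_cdsb, alpha_dsb, dna_content, loop_size,
                         n_starts, random_state, k_cov)
        self.hrf_bounds = hrf_bounds

    def _bounds(self):
        lo, hi = self.hrf_bounds
        return np.array([lo]), np.array([hi])

    def _model_params(self, theta):
        return self._base_params().with_alpha(self.alpha_dsb / theta[0]), 1.0

    def _log_model_k(self, theta, dose, k_idsb, k_cdsb):
        params = self._base_params(k_idsb, k_cdsb).with_alpha(self.alpha_dsb / theta[0])
        return np.log(analytic_mean_survival(params, dose, 1.0))


class RsfFit(_FrozenLethalityFit):
    """Fit the radiosensitization factor to a repair-impaired normoxic curve.

    The lethality parameters are frozen; the single free parameter ``rsf``
    multiplies the isolated-lesion lethality and is bounded above by
    ``1 / k_idsb`` (beyond which every isolated lesion is lethal).

    Attributes
    ----------
    rsf_ : float
    rsf_stderr_ : float
    fit_result_ : FitResult
    """

    _free = ("rsf",)

    def _bounds(self):
        return np.array([1.0]), np.array([1.0 / self.k_idsb])

    def _model_params(self, theta):
        return self._base_params(), float(theta[0])

    def _log_model_k(self, theta, dose, k_idsb, k_cdsb):
        return np.log(analytic_mean_survival(self._base_params(k_idsb, k_cdsb),
                                             dose, float(theta[0])))


# ---------------------------------------------------------------------------
# module-level wrappers over the estimators
# ---------------------------------------------------------------------------

def _weights_from_dataset(data: SurvivalDataset, weighted: bool):
    if not weighted:
        return None
    sem = data.sf_sems
    sf = data.surviving_fractions
    if np.any(~np.isfinite(sem)) or np.any(sem <= 0):
        raise ValueError("weighted fit requires a finite positive sf_sem on every record")
    sigma_log = sem / sf  # delta method: sd of ln(SF)
    return 1.0 / sigma_log**2


def fit_lethality(
    data: SurvivalDataset,
    params: ModelParameters | None = None,
    weighted: bool = False,
    n_starts: int = 5,
    random_state: int = 0,
) -> FitResult:
    """Fit (k_idsb, k_cdsb) to a normoxic, untreated survival dataset."""
    params = params or ModelParameters()
    data.check_fittable(min_distinct_doses=3)
    est = LethalityFit(
        alpha_dsb=params.alpha_dsb, dna_content=params.dna_content,
        loop_size=params.loop_size, n_starts=n_starts, random_state=random_state,
    )
    est.fit(data.doses, data.surviving_fractions,
            sample_weight=_weights_from_dataset(data, weighted))
    return est.fit_result_


def fit_hrf(
    data: SurvivalDataset,
    params: ModelParameters,
    weighted: bool = False,
    k_cov=None,
) -> FitResult:
    """Fit the HRF to a hypoxic dataset with lethalities frozen in ``params``.

    Pass ``k_cov`` (covariance of the frozen lethality estimates, e.g.
    ``fit_lethality(...).covariance``) to propagate their uncertainty into
    the reported standard error.
    """
    data.check_fittable(min_distinct_doses=3)
    est = HrfFit(
        k_idsb=params.k_idsb, k_cdsb=params.k_cdsb, alpha_dsb=params.alpha_dsb,
        dna_content=params.dna_content, loop_size=params.loop_size, k_cov=k_cov,
    )
    est.fit(data.doses, data.surviving_fractions,
            sample_weight=_weights_from_dataset(data, weighted))
    return est.fit_result_


def fit_rsf(
    data: SurvivalDataset,
    params: ModelParameters,
    weighted: bool = False,
    k_cov=None,
) -> FitResult:
    """Fit the RSF to a repair-impaired normoxic dataset with lethalities frozen.

    ``k_cov`` propagates the frozen-lethality uncertainty as in :func:`fit_hrf`.
    """
    data.check_fittable(min_distinct_doses=3)
    est = RsfFit(
        k_idsb=params.k_idsb, k_cdsb=params.k_cdsb, alpha_dsb=params.alpha_dsb,
        dna_content=params.dna_content, loop_size=params.loop_size, k_cov=k_cov,
    )
    est.fit(data.doses, data.surviving_fractions,
            sample_weight=_weights_from_dataset(data, weighted))
    return est.fit_result_


def predict_combined(
    params: ModelParameters,
    hrf: float,
    rsf: float,
    doses,
) -> np.ndarray:
    """Zero-free-parameter survival prediction for hypoxia + repair impairment.

    Applies the HRF fitted on untreated hypoxic data and the RSF fitted on
    normoxic impaired data; both are invariant under the other condition, so
    no refit is needed.
    """
    cond = OxygenCondition.fitted(hrf)
    imp = RepairImpairment(label="combined", rsf=rsf)
    adj, rsf_val = condition_adjusted_params(params, cond, imp)
    return np.asarray(analytic_mean_survival(adj, np.asarray(doses, dtype=float), rsf_val))


def lq_taylor_coefficients(
    params: ModelParameters, rsf: float = 1.0
) -> tuple[float, float]:
    """Linear-quadratic (alpha, beta) from the low-dose Taylor expansion.

    Expanding -ln E[S] of the closed form to second order in dose gives, with
    ``lam1 = alpha_dsb * loop_size`` (per-loop DSBs per Gy) and
    ``k' = rsf * k_idsb``:

        alpha = k' * alpha_dsb * dna_content                      [1/Gy]
        beta  = n_loops * lam1^2 * (k_cdsb/2 - k' + k'^2/2)       [1/Gy^2]

    so the LQ curve exp(-alpha*D - beta*D^2) matches the model at low doses.
    """
    k_eff = rsf * params.k_idsb
    if k_eff > 1.0:
        raise ValueError(f"rsf * k_idsb = {k_eff} exceeds 1")
    n_loops = loop_count(params)
    lam1 = params.alpha_dsb * params.loop_size
    alpha = k_eff * params.alpha_dsb * params.dna_content
    beta = n_loops * lam1**2 * (params.k_cdsb / 2.0 - k_eff + k_eff**2 / 2.0)
    return float(alpha), float(beta)
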