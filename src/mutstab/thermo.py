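"""Two-state folding thermodynamics linking ΔΔG to cellular observables.

The model assumes each variant equilibrates between a folded and an
unfolded state with ΔG_mut = ΔG_WT + ΔΔG, and that the folded fraction

    f(ΔΔG) = 1 / (1 + exp((ΔG_WT + ΔΔG) / RT))

(sign convention: negative ΔG = mostly folded) sets the observable —
steady-state abundance relative to wild type is f(ΔΔG)/f(0), and residual
function interpolates between a fully-folded and an unfolded anchor.
ΔG_WT is an *effective* cellular stability estimated by least squares with
a nonparametric (case-resampling) bootstrap for uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

GAS_CONSTANT_KCAL = 1.987e-3  # kcal/(mol·K)
T_37C = 310.15  # K, the culture temperature the abundance data come from
T_29C = 302.15  # K, available for the low-temperature condition

DG_WT_BOUNDS = (-15.0, 5.0)  # kcal/mol search interval for the fit

__all__ = [
    "GAS_CONSTANT_KCAL",
    "T_37C",
    "T_29C",
    "ThermoModel",
    "ThermoFitResult",
    "TwoStateAbundanceModel",
    "AnchoredSurvivalModel",
    "fit_dg_wt",
    "fit_survival",
]


@dataclass(frozen=True)
class ThermoModel:
    """Two-state model constants: effective ΔG_WT (kcal/mol), R, and T."""

    dg_wt: float
    gas_constant: float = GAS_CONSTANT_KCAL
    temperature: float = T_37C

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.gas_constant <= 0:
            raise ValueError("temperature and gas constant must be positive")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature

    def fraction_folded(self, ddg):
        """Equilibrium folded fraction at destabilization ``ddg`` (kcal/mol)."""
        x = (self.dg_wt + np.asarray(ddg, dtype=float)) / self.rt
        # logistic in -x; np.exp saturates gracefully at the extremes
        with np.errstate(over="ignore"):
            out = 1.0 / (1.0 + np.exp(x))
        return out if out.ndim else float(out)

    def predicted_level(self, ddg):
        """Steady-state abundance relative to wild type: f(ΔΔG)/f(0)."""
        out = np.asarray(self.fraction_folded(ddg)) / self.fraction_folded(0.0)
        return out if out.ndim else float(out)

    def degradation_threshold(self, level: float = 0.5) -> float:
        """ΔΔG at which the predicted relative level drops to ``level``.

        Closed form: level = f(ΔΔG)/f(0) ⇒ ΔΔG = RT·ln(1/(level·f(0)) − 1) − ΔG_WT.
        For a stable wild type (f(0) ≈ 1) and level = 0.5 this is ≈ −ΔG_WT.
        """
        if not 0.0 < level < 1.0:
            raise ValueError("level must lie strictly between 0 and 1")
        f0 = self.fraction_folded(0.0)
        target = level * f0
        if target >= 1.0:
            raise ValueError(f"relative level {level} is unreachable (f(0) = {f0:.4g})")
        return float(self.rt * np.log(1.0 / target - 1.0) - self.dg_wt)


@dataclass
class ThermoFitResult:
    """Point estimate, bootstrap distribution and diagnostics for a ΔG_WT fit."""

    dg_wt: float
    bootstrap_samples: np.ndarray
    n_bootstrap: int
    seed: int | None
    residuals: np.ndarray
    gas_constant: float
    temperature: float
    at_bound: bool
    model_name: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bootstrap_samples = np.asarray(self.bootstrap_samples, dtype=float)
        if self.bootstrap_samples.size != self.n_bootstrap:
            raise ValueError("bootstrap sample count does not match n_bootstrap")

    @property
    def bootstrap_sd(self) -> float:
        """The reported uncertainty: standard deviation of the bootstrap refits."""
        if self.n_bootstrap == 0:
            return float("nan")
        return float(np.std(self.bootstrap_samples, ddof=1)) if self.n_bootstrap > 1 else 0.0

    def percentile_band(self, level: float = 50.0) -> tuple[float, float]:
        """Central bootstrap percentile band: 50 → (25th, 75th), 95 → (2.5th, 97.5th)."""
        if self.n_bootstrap == 0:
            return (float("nan"), float("nan"))
        lo = (100.0 - level) / 2.0
        band = np.percentile(self.bootstrap_samples, [lo, 100.0 - lo])
        return float(band[0]), float(band[1])

    @property
    def model(self) -> ThermoModel:
        return ThermoModel(self.dg_wt, self.gas_constant, self.temperature)

    def degradation_threshold(self, level: float = 0.5) -> dict:
        """ΔΔG causing a drop to ``level``, with the bootstrap band propagated."""
        point = self.model.degradation_threshold(level)
        if self.n_bootstrap:
            thresholds = np.array(
                [
                    ThermoModel(d, self.gas_constant, self.temperature).degradation_threshold(level)
                    for d in self.bootstrap_samples
                ]
            )
            band50 = tuple(np.percentile(thresholds, [25, 75]))
            band95 = tuple(np.percentile(thresholds, [2.5, 97.5]))
        else:
            band50 = band95 = (float("nan"), float("nan"))
        return {"threshold": point, "band_50": band50, "band_95": band95, "level": level}

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "dg_wt": self.dg_wt,
            "bootstrap_sd": self.bootstrap_sd,
            "band_50": self.percentile_band(50),
            "band_95": self.percentile_band(95),
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
            "at_bound": self.at_bound,
            "residuals": self.residuals.tolist(),
            "gas_constant": self.gas_constant,
            "temperature": self.temperature,
            **self.extra,
        }

    def summary(self) -> str:
        b50 = self.percentile_band(50)
        b95 = self.percentile_band(95)
        lines = [
            f"{self.model_name} fit",
            "=" * 46,
            f"dg_wt (kcal/mol)      {self.dg_wt:>10.3f}",
            f"bootstrap sd          {self.bootstrap_sd:>10.3f}",
            f"25-75% band           [{b50[0]:.3f}, {b50[1]:.3f}]",
            f"2.5-97.5% band        [{b95[0]:.3f}, {b95[1]:.3f}]",
            f"n_bootstrap           {self.n_bootstrap:>10d}",
            f"seed                  {str(self.seed):>10s}",
            f"n_obs                 {self.residuals.size:>10d}",
            f"RSS                   {float(np.sum(self.residuals ** 2)):>10.4g}",
            f"optimizer at bound    {str(self.at_bound):>10s}",
        ]
        return "\n".join(lines)


class _BaseThermoFitter:
    """Shared machinery: bounded 1-D least squares plus case-resampling bootstrap."""

    model_name = "two-state"

    def __init__(
        self,
        ddg,
        observed,
        gas_constant: float = GAS_CONSTANT_KCAL,
        temperature: float = T_37C,
        bounds: tuple[float, float] = DG_WT_BOUNDS,
    ):
        self.ddg = np.asarray(ddg, dtype=float)
        self.observed = np.asarray(observed, dtype=float)
        if self.ddg.shape != self.observed.shape or self.ddg.ndim != 1:
            raise ValueError("ddg and observations must be matching 1-D arrays")
        if self.ddg.size < 3:
            raise ValueError("at least 3 variants are required for the fit")
        if not np.all(np.isfinite(self.ddg)) or not np.all(np.isfinite(self.observed)):
            raise ValueError("non-finite inputs")
        self.gas_constant = gas_constant
        self.temperature = temperature
        self.bounds = bounds

    def _predict(self, dg_wt: float, ddg: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _rss(self, dg_wt: float, ddg: np.ndarray, obs: np.ndarray) -> float:
        r = obs - self._predict(dg_wt, ddg)
        return float(np.dot(r, r))

    def _point_fit(self, ddg: np.ndarray, obs: np.ndarray) -> float:
        res = minimize_scalar(
            self._rss,
            bounds=self.bounds,
            args=(ddg, obs),
            method="bounded",
            options={"xatol": 1e-7},
        )
        return float(res.x)

    def fit(
        self,
        n_bootstrap: int = 5000,
        seed: int | None = None,
        resample_fraction: float = 1.0,
        with_replacement: bool = True,
    ) -> ThermoFitResult:
        """Least-squares ΔG_WT with a seeded case-resampling bootstrap.

        The default is the standard nonparametric bootstrap (resampling the
        variants with replacement at full size); ``with_replacement=False``
        with ``resample_fraction < 1`` gives subsampling instead.
        """
        if np.ptp(self.observed) == 0:
            raise ValueError("all observations identical; ΔG_WT is unidentifiable")
        dg_hat = self._point_fit(self.ddg, self.observed)
        at_bound = min(abs(dg_hat - b) for b in self.bounds) < 1e-4

        rng = np.random.default_rng(seed)
        n = self.ddg.size
        m = max(3, int(round(resample_fraction * n)))
        samples = np.empty(n_bootstrap, dtype=float)
        for b in range(n_bootstrap):
            idx = (
                rng.integers(0, n, size=n)
                if with_replacement
                else rng.permutation(n)[:m]
            )
            samples[b] = self._point_fit(self.ddg[idx], self.observed[idx])

        residuals = self.observed - self._predict(dg_hat, self.ddg)
        return ThermoFitResult(
            dg_wt=dg_hat,
            bootstrap_samples=samples,
            n_bootstrap=n_bootstrap,
            seed=seed,
            residuals=residuals,
            gas_constant=self.gas_constant,
            temperature=self.temperature,
            at_bound=at_bound,
            model_name=self.model_name,
            extra=self._extra(),
        )

    def _extra(self) -> dict:
        return {}


class TwoStateAbundanceModel(_BaseThermoFitter):
    """Fit ΔG_WT from relative steady-state levels vs predicted ΔΔG.

    Observed levels (wild type = 1) are modelled as f(ΔΔG)/f(0); the loss
    is ordinary least squares on the linear abundance scale. Wild type is
    included as a data point only if it is present in the input.
    """

    model_name = "two-state abundance"

    def __init__(self, ddg, levels, **kwargs):
        super().__init__(ddg, levels, **kwargs)
        if np.any(self.observed < 0):
            raise ValueError("levels must be non-negative")

    def _predict(self, dg_wt: float, ddg: np.ndarray) -> np.ndarray:
        return ThermoModel(dg_wt, self.gas_constant, self.temperature).predicted_level(ddg)


class AnchoredSurvivalModel(_BaseThermoFitter):
    """Fit ΔG_WT from residual function (% survival) with two anchors.

    survival(ΔΔG) = s_unfolded + (s_folded − s_unfolded) · f(ΔΔG)/f(0),
    where ``s_folded`` is the observed survival of the fully-folded anchor
    (the wild type; sensitive cells die, so this is low) and
    ``s_unfolded`` of the unfolded anchor (a fully non-functional variant).
    """

    model_name = "anchored survival"

    def __init__(self, ddg, survival, variants, folded_anchor: str, unfolded_anchor: str, **kwargs):
        super().__init__(ddg, survival, **kwargs)
        variants = list(variants)
        if len(variants) != self.ddg.size:
            raise ValueError("variants must align with ddg/survival")
        if np.any((self.observed < 0) | (self.observed > 100)):
            raise ValueError("survival must lie in [0, 100]")
        for anchor in (folded_anchor, unfolded_anchor):
            if anchor not in variants:
                raise ValueError(f"anchor {anchor!r} not present in the data")
        self.variants = variants
        self.s_folded = float(self.observed[variants.index(folded_anchor)])
        self.s_unfolded = float(self.observed[variants.index(unfolded_anchor)])
        if self.s_folded == self.s_unfolded:
            raise ValueError("anchors have equal survival; the model is degenerate")
        self.folded_anchor = folded_anchor
        self.unfolded_anchor = unfolded_anchor

    def _predict(self, dg_wt: float, ddg: np.ndarray) -> np.ndarray:
        level = ThermoModel(dg_wt, self.gas_constant, self.temperature).predicted_level(ddg)
        return self.s_unfolded + (self.s_folded - self.s_unfolded) * level

    def _extra(self) -> dict:
        return {
            "s_folded": self.s_folded,
            "s_unfolded": self.s_unfolded,
            "folded_anchor": self.folded_anchor,
            "unfolded_anchor": self.unfolded_anchor,
        }


def fit_dg_wt(ddg, levels, n_bootstrap: int = 5000, seed: int | None = None, **kwargs) -> ThermoFitResult:
    """Functional wrapper around :class:`TwoStateAbundanceModel`."""
    return TwoStateAbundanceModel(ddg, levels, **kwargs).fit(n_bootstrap=n_bootstrap, seed=seed)


def fit_survival(
    ddg,
    survival,
    variants,
    folded_anchor: str,
    unfolded_anchor: str,
    n_bootstrap: int = 5000,
    seed: int | None = None,
    **kwargs,
) -> ThermoFitResult:
    """Functional wrapper around :class:`AnchoredSurvivalModel`."""
    model = AnchoredSurvivalModel(ddg, survival, variants, folded_anchor, unfolded_anchor, **kwargs)
    return model.fit(n_bootstrap=n_bootstrap, seed=seed)
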