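"""Equilibrium binding and competition-assay analysis.

Three computations mirror how TCR-pMHC affinities are measured:

* steady-state SPR: the equilibrium response at analyte concentration C
  follows the one-site isotherm R_eq(C) = R_max * C / (K_D + C); a
  nonlinear least-squares fit over the pooled replicate points yields
  K_D with a Jacobian-based standard error;
* fluorescence-polarization competition: normalized relative binding
  follows a four-parameter logistic (sigmoidal dose-response) in the
  competitor concentration; IC50 is the inflection concentration, and
  a curve whose lower plateau stays above a residual-binding floor is
  flagged as not reaching full inhibition;
* mutational impact: the fold change K_D(mutant)/K_D(wild-type) is
  binned into no_effect (<2), moderate (2-5), severe (5-10) and
  deleterious (>=10), left-closed at the boundaries.

All fits are unweighted; reference-cell subtraction and control
normalization are assumed done upstream (or via
:func:`normalize_relative_binding`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "BindingCurve",
    "KdFit",
    "CompetitionCurve",
    "Ic50Fit",
    "ImpactClass",
    "IMPACT_BINS",
    "fit_steady_state",
    "fit_competition",
    "classify_impact",
    "normalize_relative_binding",
    "one_site",
    "four_pl",
    "read_binding_csv",
    "read_competition_csv",
]


# ---------------------------------------------------------------------------
# model functions

def one_site(conc: np.ndarray, kd: float, rmax: float) -> np.ndarray:
    """One-site specific binding isotherm: R = Rmax * C / (KD + C)."""
    conc = np.asarray(conc, dtype=float)
    return rmax * conc / (kd + conc)


def four_pl(conc: np.ndarray, ic50: float, hill: float,
            top: float, bottom: float) -> np.ndarray:
    """Four-parameter logistic dose-response (decreasing for hill > 0):
    y = bottom + (top - bottom) / (1 + (C / IC50)**hill)."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)


# ---------------------------------------------------------------------------
# containers

@dataclass
class BindingCurve:
    """Equilibrium SPR responses: concentration (uM) vs response (RU)."""

    concentrations: np.ndarray
    responses: np.ndarray
    replicate_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.replicate_id is None:
            self.replicate_id = np.zeros(len(self.concentrations), dtype=int)
        else:
            self.replicate_id = np.asarray(self.replicate_id)
        if len(self.concentrations) != len(self.responses):
            raise ValueError("concentration/response length mismatch")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("non-finite responses")

    @property
    def n_distinct(self) -> int:
        return len(np.unique(self.concentrations))


@dataclass
class KdFit:
    kd: float
    rmax: float
    se_kd: float
    se_rmax: float
    rss: float
    converged: bool
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "kd_uM": float(f"{self.kd:.3g}"),
            "rmax_RU": float(f"{self.rmax:.3g}"),
            "se_kd_uM": float(f"{self.se_kd:.3g}"),
            "se_rmax_RU": float(f"{self.se_rmax:.3g}"),
            "rss": float(f"{self.rss:.4g}"),
            "converged": self.converged,
            "message": self.message,
        }


@dataclass
class CompetitionCurve:
    """Competitor concentration (uM) vs normalized relative binding (%)."""

    competitor_conc: np.ndarray
    normalized_binding: np.ndarray
    replicate_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.competitor_conc = np.asarray(self.competitor_conc, dtype=float)
        self.normalized_binding = np.asarray(self.normalized_binding, dtype=float)
        if self.replicate_id is None:
            self.replicate_id = np.zeros(len(self.competitor_conc), dtype=int)
        else:
            self.replicate_id = np.asarray(self.replicate_id)
        if len(self.competitor_conc) != len(self.normalized_binding):
            raise ValueError("concentration/binding length mismatch")
        if np.any(self.competitor_conc <= 0):
            raise ValueError("competitor concentrations must be positive")


@dataclass
class Ic50Fit:
    ic50: float
    hill: float
    top: float
    bottom: float
    se_ic50: float
    reached_full_inhibition: bool
    unbounded: bool = False  # no inhibition detected within tested range
    max_tested: float = float("nan")
    converged: bool = True
    message: str = ""

    def to_dict(self) -> dict:
        out = {
            "ic50_uM": (
                f"> {self.max_tested:g}" if self.unbounded
                else float(f"{self.ic50:.3g}")
            ),
            "hill": float(f"{self.hill:.3g}"),
            "top_pct": round(self.top, 1),
            "bottom_pct": round(self.bottom, 1),
            "se_ic50_uM": float(f"{self.se_ic50:.3g}") if np.isfinite(self.se_ic50) else None,
            "reached_full_inhibition": self.reached_full_inhibition,
            "converged": self.converged,
            "message": self.message,
        }
        return out


#: left-closed fold-change bins for mutant affinity impact
IMPACT_BINS: tuple[tuple[float, float, str], ...] = (
    (0.0, 2.0, "no_effect"),
    (2.0, 5.0, "moderate"),
    (5.0, 10.0, "severe"),
    (10.0, float("inf"), "deleterious"),
)


@dataclass
class ImpactClass:
    fold: float
    label: str
    note: str = ""


# ---------------------------------------------------------------------------
# fitting

def fit_steady_state(curve: BindingCurve, *, pooled: bool = True) -> KdFit:
    """Fit the one-site isotherm to equilibrium responses.

    Replicate points are fitted jointly when ``pooled`` (the default);
    with ``pooled=False`` each replicate is fitted separately and the
    per-replicate K_D values are averaged (geometric mean), matching
    the alternative per-experiment analysis convention.

    Initialization: K_D from the concentration nearest half-maximal
    response, R_max at 1.1x the maximum observed response.
    """
    if curve.n_distinct < 5:
        raise ValueError(
            f"need >= 5 distinct concentrations, got {curve.n_distinct}"
        )
    span = curve.concentrations.max() / curve.concentrations.min()
    if span < 10:
        warnings.warn(
            f"concentration series spans only {span:.1f}x; K_D may be poorly "
            "constrained", stacklevel=2,
        )

    if not pooled:
        fits = [
            fit_steady_state(
                BindingCurve(
                    curve.concentrations[curve.replicate_id == rep],
                    curve.responses[curve.replicate_id == rep],
                ),
                pooled=True,
            )
            for rep in np.unique(curve.replicate_id)
        ]
        kds = np.array([f.kd for f in fits])
        rmaxs = np.array([f.rmax for f in fits])
        return KdFit(
            kd=float(np.exp(np.mean(np.log(kds)))),
            rmax=float(rmaxs.mean()),
            se_kd=float(kds.std(ddof=1) / np.sqrt(len(kds))) if len(kds) > 1 else 0.0,
            se_rmax=float(rmaxs.std(ddof=1) / np.sqrt(len(rmaxs))) if len(rmaxs) > 1 else 0.0,
            rss=float(sum(f.rss for f in fits)),
            converged=all(f.converged for f in fits),
            message="per-replicate fits averaged",
        )

    conc, resp = curve.concentrations, curve.responses
    rmax0 = 1.1 * resp.max() if resp.max() > 0 else 1.0
    half = 0.5 * resp.max()
    kd0 = float(conc[np.argmin(np.abs(resp - half))])
    kd0 = max(kd0, conc.min() * 1e-3)
    try:
        popt, pcov = curve_fit(
            one_site, conc, resp, p0=[kd0, rmax0],
            bounds=([1e-9, 1e-9], [np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:
        return KdFit(
            kd=float("nan"), rmax=float("nan"), se_kd=float("nan"),
            se_rmax=float("nan"), rss=float("nan"), converged=False,
            message=f"fit did not converge: {exc}",
        )
    kd, rmax = popt
    perr = np.sqrt(np.diag(pcov))
    rss = float(np.sum((resp - one_site(conc, *popt)) ** 2))
    return KdFit(
        kd=float(kd), rmax=float(rmax),
        se_kd=float(perr[0]), se_rmax=float(perr[1]),
        rss=rss, converged=True,
    )


def fit_competition(
    curve: CompetitionCurve,
    *,
    residual_floor: float = 20.0,
    inhibition_threshold: float = 25.0,
    fix_hill: float | None = None,
) -> Ic50Fit:
    """Fit a four-parameter logistic to a competition curve.

    ``reached_full_inhibition`` is False when the fitted bottom plateau
    exceeds ``residual_floor`` percent residual binding. If the curve
    never drops by more than ``inhibition_threshold`` percent within
    the tested range, the IC50 is reported as unbounded
    ("> max tested") rather than an extrapolated number.
    ``fix_hill`` pins the slope (e.g. 1.0 for the classic fixed-slope
    sigmoidal dose-response model) instead of fitting it.

    Initialization: IC50 at the geometric mean of tested concentrations,
    hill 1, plateaus from the observed extremes.
    """
    conc, y = curve.competitor_conc, curve.normalized_binding
    if len(np.unique(conc)) < 6:
        raise ValueError("need >= 6 distinct competitor concentrations")

    # monotonicity sanity check (inhibition should decrease binding)
    order = np.argsort(conc)
    med = pd.Series(y[order]).rolling(3, center=True, min_periods=1).median().to_numpy()
    if np.any(np.diff(med) > 15.0):
        warnings.warn("competition curve rises with concentration beyond noise",
                      stacklevel=2)

    drop = y[conc <= np.median(conc)].mean() - y[conc >= np.quantile(conc, 0.9)].mean()
    max_tested = float(conc.max())
    if drop < inhibition_threshold and y.min() > 100.0 - inhibition_threshold:
        return Ic50Fit(
            ic50=float("inf"), hill=float("nan"), top=float(np.mean(y)),
            bottom=float(np.mean(y)), se_ic50=float("nan"),
            reached_full_inhibition=False, unbounded=True,
            max_tested=max_tested, converged=True,
            message=f"no inhibition detected; IC50 > {max_tested:g} uM",
        )

    ic50_0 = float(np.exp(np.mean(np.log(conc))))
    top0 = float(np.percentile(y, 95))
    bot0 = float(np.percentile(y, 5))
    try:
        if fix_hill is None:
            popt, pcov = curve_fit(
                four_pl, conc, y, p0=[ic50_0, 1.0, top0, bot0],
                bounds=([1e-9, 0.1, 0.0, -20.0], [np.inf, 10.0, 150.0, 100.0]),
                maxfev=20000,
            )
            ic50, hill, top, bottom = (float(v) for v in popt)
        else:
            model = lambda c, ic, t, b: four_pl(c, ic, fix_hill, t, b)  # noqa: E731
            popt, pcov = curve_fit(
                model, conc, y, p0=[ic50_0, top0, bot0],
                bounds=([1e-9, 0.0, -20.0], [np.inf, 150.0, 100.0]),
                maxfev=20000,
            )
            ic50, top, bottom = (float(v) for v in popt)
            hill = float(fix_hill)
    except RuntimeError as exc:
        return Ic50Fit(
            ic50=float("nan"), hill=float("nan"), top=float("nan"),
            bottom=float("nan"), se_ic50=float("nan"),
            reached_full_inhibition=False, converged=False,
            max_tested=max_tested, message=f"fit did not converge: {exc}",
        )
    se_ic50 = float(np.sqrt(pcov[0, 0]))
    return Ic50Fit(
        ic50=ic50, hill=hill, top=top, bottom=bottom, se_ic50=se_ic50,
        reached_full_inhibition=bottom <= residual_floor,
        max_tested=max_tested,
    )


def classify_impact(kd_mut: float, kd_wt: float) -> ImpactClass:
    """Bin a mutant's affinity change relative to wild type.

    fold = K_D(mutant) / K_D(wild-type); bins are left-closed:
    [0,2) no_effect, [2,5) moderate, [5,10) severe, [10,inf) deleterious.
    A fold below 1 (improved affinity) is no_effect with an "improved"
    note.
    """
    if kd_mut <= 0 or kd_wt <= 0:
        raise ValueError("K_D values must be positive")
    fold = kd_mut / kd_wt
    for lo, hi, label in IMPACT_BINS:
        if lo <= fold < hi:
            return ImpactClass(
                fold=fold, label=label,
                note="improved" if fold < 1 else "",
            )
    return ImpactClass(fold=fold, label="deleterious")


def normalize_relative_binding(
    raw_polarization: np.ndarray,
    zero_ctrl: float,
    full_ctrl: float,
    competitor_conc: np.ndarray | None = None,
    replicate_id: np.ndarray | None = None,
) -> np.ndarray | CompetitionCurve:
    """Map raw polarization onto percent relative binding.

    Linear map sending the no-binding control to 0% and the
    uninhibited control to 100%; invariant under any affine transform
    applied to both the data and the controls.
    """
    if zero_ctrl == full_ctrl:
        raise ValueError("normalization controls must be distinct")
    raw = np.asarray(raw_polarization, dtype=float)
    pct = 100.0 * (raw - zero_ctrl) / (full_ctrl - zero_ctrl)
    if competitor_conc is None:
        return pct
    return CompetitionCurve(competitor_conc, pct, replicate_id)


# ---------------------------------------------------------------------------
# CSV I/O (columns: concentration_uM, response[, replicate])

def read_binding_csv(path: str | Path) -> BindingCurve:
    df = _read_curve_csv(path, "response")
    return BindingCurve(
        df["concentration_uM"].to_numpy(),
        df["response"].to_numpy(),
        df["replicate"].to_numpy(),
    )


def read_competition_csv(path: str | Path) -> CompetitionCurve:
    df = _read_curve_csv(path, "response")
    return CompetitionCurve(
        df["concentration_uM"].to_numpy(),
        df["response"].to_numpy(),
        df["replicate"].to_numpy(),
    )


def _read_curve_csv(path: str | Path, value_col: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"concentration_uM", value_col}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = 0
    bad = df.index[~np.isfinite(df["concentration_uM"]) | ~np.isfinite(df[value_col])]
    if len(bad):
        raise ValueError(f"{path}: malformed values at row(s) {list(bad[:5])}")
    return df
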