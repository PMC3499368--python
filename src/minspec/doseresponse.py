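"""Reporter-assay normalization and dose-response structure-activity analysis.

Implements the quantitative stage of a receptor/ligand specificity study:
dual-luciferase normalization to fold activation over the vehicle control,
four-parameter logistic (4PL) agonist fits yielding EC50 with a Wald
confidence interval on log10 EC50, descending 4PL inhibition (IC50) fits,
matched-pair fold preferences between ligands differing by one chemical
moiety, and classification of ligand-recognition rules from those fold
preferences.

The 4PL is parameterized in log10-dose space,

    response(d) = basal + (max - basal) / (1 + 10**((log10 EC50 - log10 d) * hill)),

and fitted by least squares on log responses (multiplicative, log-normal
error assumption, appropriate for luciferase ratios). Hill slopes are
bounded to [0.3, 5] in magnitude to prevent degenerate fits on sparse
dose grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from os import PathLike

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import f as f_dist, t as t_dist

__all__ = [
    "AssayTable",
    "NormalizedResponse",
    "DoseResponseFit",
    "InhibitionFit",
    "FoldPreference",
    "RecognitionRule",
    "read_assay_tables",
    "normalize_reporter",
    "fit_dose_response",
    "fit_inhibition",
    "fold_preference",
    "infer_recognition_rules",
]

HILL_BOUNDS = (0.3, 5.0)


@dataclass
class AssayTable:
    """Triplicate dual-luciferase readings for one receptor/ligand series."""

    receptor: str
    ligand: str
    doses: np.ndarray  # molar, ascending
    firefly: np.ndarray  # (n_doses, n_replicates)
    renilla: np.ndarray  # (n_doses, n_replicates)
    vehicle_firefly: np.ndarray  # (n_replicates,)
    vehicle_renilla: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.firefly = np.atleast_2d(np.asarray(self.firefly, dtype=float))
        self.renilla = np.atleast_2d(np.asarray(self.renilla, dtype=float))
        self.vehicle_firefly = np.asarray(self.vehicle_firefly, dtype=float)
        self.vehicle_renilla = np.asarray(self.vehicle_renilla, dtype=float)
        if np.any(self.doses <= 0):
            raise ValueError("doses must be strictly positive molar concentrations")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly ascending")
        if len(self.doses) < 2:
            raise ValueError("need at least two dose levels")
        if self.firefly.shape != self.renilla.shape or self.firefly.shape[0] != len(self.doses):
            raise ValueError("firefly/renilla shapes must be (n_doses, n_replicates)")
        if self.vehicle_firefly.size == 0:
            raise ValueError("vehicle-control wells are required")
        bad = np.argwhere(self.renilla <= 0)
        if bad.size:
            d, r = bad[0]
            raise ValueError(
                f"nonpositive Renilla reading at dose index {d}, replicate {r}"
            )
        if np.any(self.vehicle_renilla <= 0):
            raise ValueError("nonpositive Renilla reading in a vehicle well")


@dataclass
class NormalizedResponse:
    """Fold activation over vehicle, per dose."""

    doses: np.ndarray
    fold: np.ndarray  # (n_doses, n_replicates)
    mean: np.ndarray
    sem: np.ndarray


@dataclass
class DoseResponseFit:
    """4PL agonist fit: EC50 (M) with 95% CI, Hill slope, plateaus."""

    ec50: float | None
    ec50_ci: tuple[float, float] | None
    hill: float | None
    basal: float | None
    max_response: float | None
    log10_ec50_se: float | None
    converged: bool
    no_activation: bool
    residual_sd: float | None
    n_obs: int
    note: str = ""

    @property
    def determined(self) -> bool:
        return self.converged and not self.no_activation and self.ec50 is not None


@dataclass
class InhibitionFit:
    """Descending 4PL fit: IC50 (M) in the presence of a fixed agonist dose."""

    ic50: float | None
    ic50_ci: tuple[float, float] | None
    hill: float | None
    top: float | None
    bottom: float | None
    agonist: str
    agonist_concentration: float
    converged: bool
    no_inhibition: bool
    monotone_warning: bool = False


@dataclass
class FoldPreference:
    """EC50 ratio between two ligands differing by a single moiety.

    ``fold = ec50_b / ec50_a``: fold > 1 means ligand ``a`` is preferred
    (activates at lower concentration).
    """

    ligand_a: str
    ligand_b: str
    moiety: str
    fold: float
    fold_ci: tuple[float, float] | None
    censored: bool = False
    note: str = ""


@dataclass
class RecognitionRule:
    """A ligand-recognition criterion inferred from matched-pair folds."""

    moiety: str
    direction: str  # "required" | "excluded" | "preferred-weak" | "inconsistent" | "none"
    supporting_pairs: list[FoldPreference] = field(default_factory=list)
    min_fold: float = 1.0
    strength: str = "weak"  # "strong" | "weak"

    def bracket(self) -> str:
        """Bracket-style rendering, e.g. ``[aromatized A-ring]`` or ``[not 11-OH]``."""
        if self.direction == "required":
            return f"[{self.moiety}]"
        if self.direction == "excluded":
            return f"[not {self.moiety}]"
        return f"[({self.moiety}: {self.direction})]"


# ---------------------------------------------------------------------------
# I/O and normalization
# ---------------------------------------------------------------------------

def read_assay_tables(path: str | PathLike) -> list[AssayTable]:
    """Read a TSV of raw assay wells into per-(receptor, ligand) tables.

    Expected columns: receptor, ligand, dose_M, firefly, renilla,
    is_vehicle (0/1). Vehicle wells are shared across ligands of the same
    receptor when their ligand field is empty or 'vehicle'.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"receptor", "ligand", "dose_M", "firefly", "renilla", "is_vehicle"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    tables = []
    for receptor, rgroup in df.groupby("receptor"):
        veh = rgroup[rgroup["is_vehicle"].astype(bool)]
        if veh.empty:
            raise ValueError(f"no vehicle-control wells for receptor {receptor!r}")
        for ligand, group in rgroup[~rgroup["is_vehicle"].astype(bool)].groupby("ligand"):
            doses = np.array(sorted(group["dose_M"].unique()))
            ff, rr = [], []
            for d in doses:
                sel = group[group["dose_M"] == d].sort_index()
                ff.append(sel["firefly"].to_numpy())
                rr.append(sel["renilla"].to_numpy())
            n_rep = {len(x) for x in ff}
            if len(n_rep) != 1:
                raise ValueError(
                    f"inconsistent replicate counts for {receptor}/{ligand}: {sorted(n_rep)}"
                )
            tables.append(
                AssayTable(
                    receptor=receptor,
                    ligand=ligand,
                    doses=doses,
                    firefly=np.vstack(ff),
                    renilla=np.vstack(rr),
                    vehicle_firefly=veh["firefly"].to_numpy(),
                    vehicle_renilla=veh["renilla"].to_numpy(),
                )
            )
    return tables


def normalize_reporter(table: AssayTable) -> NormalizedResponse:
    """Fold activation: (firefly/Renilla) relative to the vehicle mean.

    Each well's firefly reading is normalized by its Renilla reading, and
    the resulting ratios are divided by the mean vehicle ratio, so a fold
    of 1 means vehicle-level activity.
    """
    ratio = table.firefly / table.renilla
    vehicle = float(np.mean(table.vehicle_firefly / table.vehicle_renilla))
    if vehicle <= 0:
        raise ValueError("vehicle-control ratio is nonpositive")
    fold = ratio / vehicle
    mean = fold.mean(axis=1)
    n = fold.shape[1]
    sem = fold.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return NormalizedResponse(doses=table.doses, fold=fold, mean=mean, sem=sem)


# ---------------------------------------------------------------------------
# 4PL fitting
# ---------------------------------------------------------------------------

def four_parameter_logistic(log10_dose, basal, maximum, log10_ec50, hill):
    return basal + (maximum - basal) / (1.0 + 10.0 ** ((log10_ec50 - log10_dose) * hill))


def _log_4pl(log10_dose, basal, maximum, log10_ec50, hill):
    return np.log(np.maximum(four_parameter_logistic(log10_dose, basal, maximum, log10_ec50, hill), 1e-12))


def _flatten(doses: np.ndarray, fold: np.ndarray):
    logd = np.repeat(np.log10(doses), fold.shape[1])
    y = fold.ravel()
    return logd, y


def _fit(logd, y, ascending: bool):
    """Shared 4PL least-squares fit on log responses."""
    lo_y, hi_y = float(np.min(y)), float(np.max(y))
    span = hi_y - lo_y
    half = lo_y + span / 2.0
    means = pd.Series(y).groupby(logd).mean()
    crossing = means.index[np.argmin(np.abs(means.values - half))]
    hill0 = 1.0 if ascending else -1.0
    p0 = [max(lo_y, 1e-6), hi_y, float(crossing), hill0]
    if ascending:
        hill_bounds = HILL_BOUNDS
    else:
        hill_bounds = (-HILL_BOUNDS[1], -HILL_BOUNDS[0])
    bounds = (
        [1e-9, 1e-9, logd.min() - 6.0, hill_bounds[0]],
        [hi_y * 10 + 1, hi_y * 10 + 1, logd.max() + 6.0, hill_bounds[1]],
    )
    p0 = np.clip(p0, bounds[0], bounds[1])
    ylog = np.log(np.maximum(y, 1e-12))
    popt, pcov = curve_fit(_log_4pl, logd, ylog, p0=p0, bounds=bounds, maxfev=20000)
    resid = ylog - _log_4pl(logd, *popt)
    dof = max(len(y) - 4, 1)
    sd = float(np.sqrt(resid @ resid / dof))
    return popt, pcov, resid, sd, dof


def _signal_test(logd, ylog, resid_full, dof_full) -> float:
    """Extra-sum-of-squares F test of the 4PL against a flat (no-signal) model."""
    sse_full = float(resid_full @ resid_full)
    sse_flat = float(((ylog - ylog.mean()) ** 2).sum())
    df_flat = len(ylog) - 1
    num = max(sse_flat - sse_full, 0.0) / max(df_flat - dof_full, 1)
    den = sse_full / dof_full if dof_full else np.inf
    if den == 0:
        return 0.0 if num > 0 else 1.0
    return float(f_dist.sf(num / den, df_flat - dof_full, dof_full))


def fit_dose_response(
    response: NormalizedResponse,
    signal_alpha: float = 0.05,
) -> DoseResponseFit:
    """Fit an ascending 4PL to normalized fold-activation data.

    When the dose-dependent signal is not distinguishable from a flat
    response (extra-sum-of-squares F test at ``signal_alpha``) the fit is
    flagged ``no_activation`` and the EC50 is reported as not determined,
    mirroring the open-symbol convention for unresponsive receptor/ligand
    combinations.
    """
    if len(response.doses) < 4:
        warnings.warn("fewer than 4 dose levels; 4PL fit may be unstable")
    logd, y = _flatten(response.doses, response.fold)
    ylog = np.log(np.maximum(y, 1e-12))
    try:
        popt, pcov, resid, sd, dof = _fit(logd, y, ascending=True)
    except RuntimeError as err:
        return DoseResponseFit(
            ec50=None, ec50_ci=None, hill=None, basal=None, max_response=None,
            log10_ec50_se=None, converged=False, no_activation=False,
            residual_sd=None, n_obs=len(y), note=f"fit failed: {err}",
        )
    basal, maximum, log_ec50, hill = popt
    p_signal = _signal_test(logd, ylog, resid, dof)
    if p_signal > signal_alpha or maximum - basal <= 0:
        return DoseResponseFit(
            ec50=None, ec50_ci=None, hill=None, basal=float(basal),
            max_response=float(maximum), log10_ec50_se=None, converged=True,
            no_activation=True, residual_sd=sd, n_obs=len(y),
            note=f"no dose-dependent activation (F-test p = {p_signal:.3g})",
        )
    se = float(np.sqrt(max(pcov[2, 2], 0.0)))
    tcrit = float(t_dist.ppf(0.975, dof))
    ci = (10 ** (log_ec50 - tcrit * se), 10 ** (log_ec50 + tcrit * se))
    note = ""
    if log_ec50 > np.log10(response.doses).max():
        note = "EC50 beyond the tested dose range; treat as a censored lower bound"
    return DoseResponseFit(
        ec50=float(10 ** log_ec50),
        ec50_ci=ci,
        hill=float(hill),
        basal=float(basal),
        max_response=float(maximum),
        log10_ec50_se=se,
        converged=True,
        no_activation=False,
        residual_sd=sd,
        n_obs=len(y),
        note=note,
    )


def fit_inhibition(
    response: NormalizedResponse,
    agonist: str,
    agonist_concentration: float,
    signal_alpha: float = 0.05,
) -> InhibitionFit:
    """Fit a descending 4PL to inhibition data under a fixed agonist dose."""
    logd, y = _flatten(response.doses, response.fold)
    ylog = np.log(np.maximum(y, 1e-12))
    monotone_warning = bool(np.any(np.diff(response.mean) > 0.25 * np.ptp(response.mean)))
    try:
        popt, pcov, resid, sd, dof = _fit(logd, y, ascending=False)
    except RuntimeError:
        return InhibitionFit(
            ic50=None, ic50_ci=None, hill=None, top=None, bottom=None,
            agonist=agonist, agonist_concentration=agonist_concentration,
            converged=False, no_inhibition=False, monotone_warning=monotone_warning,
        )
    bottom, top, log_ic50, hill = popt
    p_signal = _signal_test(logd, ylog, resid, dof)
    if p_signal > signal_alpha or top - bottom <= 0:
        return InhibitionFit(
            ic50=None, ic50_ci=None, hill=None, top=float(top), bottom=float(bottom),
            agonist=agonist, agonist_concentration=agonist_concentration,
            converged=True, no_inhibition=True, monotone_warning=monotone_warning,
        )
    se = float(np.sqrt(max(pcov[2, 2], 0.0)))
    tcrit = float(t_dist.ppf(0.975, dof))
    return InhibitionFit(
        ic50=float(10 ** log_ic50),
        ic50_ci=(10 ** (log_ic50 - tcrit * se), 10 ** (log_ic50 + tcrit * se)),
        hill=float(hill),
        top=float(top),
        bottom=float(bottom),
        agonist=agonist,
        agonist_concentration=agonist_concentration,
        converged=True,
        no_inhibition=False,
        monotone_warning=monotone_warning,
    )


# ---------------------------------------------------------------------------
# fold preferences and recognition rules
# ---------------------------------------------------------------------------

def fold_preference(
    fit_a: DoseResponseFit,
    fit_b: DoseResponseFit,
    moiety: str,
    ligand_a: str = "a",
    ligand_b: str = "b",
    max_dose: float = 1e-5,
) -> FoldPreference:
    """Fold preference ``EC50_b / EC50_a`` with a propagated 95% CI.

    When one ligand produced no determinate EC50 up to ``max_dose`` the
    fold is reported as a censored one-sided bound (orders-of-magnitude
    style) rather than a point estimate.
    """
    if fit_a.determined and fit_b.determined:
        fold = fit_b.ec50 / fit_a.ec50
        var = (fit_a.log10_ec50_se or 0.0) ** 2 + (fit_b.log10_ec50_se or 0.0) ** 2
        half = 1.959963984540054 * np.sqrt(var)
        log_fold = np.log10(fold)
        ci = (10 ** (log_fold - half), 10 ** (log_fold + half))
        return FoldPreference(ligand_a, ligand_b, moiety, float(fold), ci)
    if fit_a.determined and not fit_b.determined:
        bound = max_dose / fit_a.ec50
        return FoldPreference(
            ligand_a, ligand_b, moiety, float(bound), None, censored=True,
            note=f">{bound:.3g}-fold (no {ligand_b} activation up to {max_dose:g} M)",
        )
    if fit_b.determined and not fit_a.determined:
        bound = fit_b.ec50 / max_dose
        return FoldPreference(
            ligand_a, ligand_b, moiety, float(bound), None, censored=True,
            note=f"<{bound:.3g}-fold (no {ligand_a} activation up to {max_dose:g} M)",
        )
    raise ValueError("neither ligand produced a determinate EC50; no fold preference")


def infer_recognition_rules(
    preferences: list[FoldPreference],
    strong_threshold: float = 10.0,
) -> list[RecognitionRule]:
    """Classify ligand-recognition rules from moiety-matched fold preferences.

    Pairs must be oriented so ligand ``a`` carries the moiety. Per moiety:
    all folds > 1 means the moiety increases sensitivity ("required" when
    the weakest supporting fold meets ``strong_threshold``); all folds < 1
    means it reduces sensitivity ("excluded" / "not <moiety>"); mixed signs
    yield "inconsistent"; folds near 1 yield "none". A single pair exactly
    at the threshold is classified strong (>= convention).
    """
    by_moiety: dict[str, list[FoldPreference]] = {}
    for p in preferences:
        by_moiety.setdefault(p.moiety, []).append(p)
    rules = []
    for moiety, pairs in by_moiety.items():
        folds = np.array([p.fold for p in pairs], dtype=float)
        if np.all(folds > 1.0):
            min_fold = float(folds.min())
            strong = min_fold >= strong_threshold
            rules.append(
                RecognitionRule(
                    moiety=moiety,
                    direction="required" if strong else "preferred-weak",
                    supporting_pairs=pairs,
                    min_fold=min_fold,
                    strength="strong" if strong else "weak",
                )
            )
        elif np.all(folds < 1.0):
            min_fold = float((1.0 / folds).min())
            strong = min_fold >= strong_threshold
            rules.append(
                RecognitionRule(
                    moiety=moiety,
                    direction="excluded" if strong else "preferred-weak",
                    supporting_pairs=pairs,
                    min_fold=min_fold,
                    strength="strong" if strong else "weak",
                )
            )
        elif np.all(folds == 1.0):
            rules.append(
                RecognitionRule(moiety=moiety, direction="none",
                                supporting_pairs=pairs, min_fold=1.0, strength="weak")
            )
        else:
            rules.append(
                RecognitionRule(moiety=moiety, direction="inconsistent",
                                supporting_pairs=pairs,
                                min_fold=float(np.min(np.maximum(folds, 1 / folds))),
                                strength="weak")
            )
    return rules
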