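"""1:1 binding-model fits used for hit confirmation, plus assay simulators.

Closed forms fitted here:

* SPR / BLI steady state:  R(C) = Rmax * C / (C + KD)
* SPR / BLI kinetics (global across concentrations, shared ka, kd, Rmax):
    association   R(t) = C*Rmax/(C + KD) * (1 - exp(-(ka*C + kd) * t))
    dissociation  R(t) = R0 * exp(-kd * t)          with KD = kd / ka
* DSF melt (Boltzmann sigmoid):  F(T) = Fmin + (Fmax - Fmin) / (1 + exp((Tm - T)/slope))
* FP displacement (4-parameter logistic, decreasing):
    P(x) = bottom + (top - bottom) / (1 + (x / IC50)^h),   Kdisp ≡ IC50

Kdisp is reported as the logistic inflection; a Cheng–Prusoff correction to
a true Ki would additionally need the probe's KD and concentration and is
offered as an explicit post-hoc helper rather than a default.

The selectivity matrix normalizes observed SPR responses at a fixed dose to
the theoretical saturation response R_max,theoretical = immobilization
level x MW(analyte)/MW(ligand), reporting mean percent binding across
replicates, clamped to [0, 120] with an over-range flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares


@dataclass
class TitrationSeries:
    concentrations: np.ndarray  # molar (dose for FP, temperature handled separately)
    responses: np.ndarray
    kind: str = "spr_steady_state"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must have equal length")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")


@dataclass
class Sensorgram:
    time: np.ndarray                       # seconds, shared grid
    traces: dict[float, np.ndarray]        # concentration -> response trace
    association_window: tuple[float, float]
    dissociation_window: tuple[float, float]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        t0, t1 = self.association_window
        d0, d1 = self.dissociation_window
        if not (self.time[0] <= t0 < t1 <= d0 < d1 <= self.time[-1]):
            raise ValueError("association/dissociation windows must tile the time grid in order")
        for c, tr in self.traces.items():
            if np.asarray(tr).shape != self.time.shape:
                raise ValueError(f"trace at {c} not aligned with time grid")


@dataclass
class FitResult:
    parameters: dict[str, float]
    stderr: dict[str, float]
    residual_norm: float
    converged: bool
    flags: list[str] = field(default_factory=list)

    def __getitem__(self, key: str) -> float:
        return self.parameters[key]


def _stderr_from_cov(pcov: np.ndarray, names: list[str]) -> dict[str, float]:
    if pcov is None or not np.all(np.isfinite(pcov)):
        return {n: np.inf for n in names}
    return {n: float(np.sqrt(max(pcov[i, i], 0.0))) for i, n in enumerate(names)}


# ---------------------------------------------------------------------------
# Steady state
# ---------------------------------------------------------------------------

def steady_state_model(conc, kd, rmax):
    return rmax * conc / (conc + kd)


def fit_steady_state(ts: TitrationSeries) -> FitResult:
    """Least-squares 1:1 steady-state affinity fit (KD, Rmax > 0)."""
    c, r = ts.concentrations, ts.responses
    if c.size < 4:
        raise ValueError("need at least 4 concentrations")
    p0 = [np.median(c), max(r.max(), 1e-12)]
    try:
        popt, pcov = curve_fit(
            steady_state_model, c, r, p0=p0,
            bounds=([1e-15, 1e-15], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError:
        return FitResult({}, {}, np.inf, converged=False, flags=["optimizer_failed"])
    resid = r - steady_state_model(c, *popt)
    flags = []
    converged = True
    # no curvature: the response never bends toward saturation over the
    # titrated range, so KD is unbounded above and the fit is uninformative
    if popt[0] > 50.0 * c.max():
        converged = False
        flags.append("no_curvature")
    return FitResult(
        {"KD": float(popt[0]), "Rmax": float(popt[1])},
        _stderr_from_cov(pcov, ["KD", "Rmax"]),
        float(np.linalg.norm(resid)),
        converged,
        flags,
    )


# ---------------------------------------------------------------------------
# Kinetics (global 1:1 Langmuir)
# ---------------------------------------------------------------------------

def association_model(t, conc, ka, kd, rmax):
    kobs = ka * conc + kd
    req = conc * rmax / (conc + kd / ka)
    return req * (1.0 - np.exp(-kobs * t))


def dissociation_model(t, r0, kd):
    return r0 * np.exp(-kd * t)


def fit_kinetic_1to1(sg: Sensorgram) -> FitResult:
    """Global 1:1 kinetic fit: shared (ka, kd, Rmax), per-curve R0.

    Association and dissociation windows of every concentration trace are
    fitted simultaneously; KD is reported as kd/ka.  Parameters are fitted
    in log-space to keep them positive across widely differing scales.
    """
    t = sg.time
    a0, a1 = sg.association_window
    d0, d1 = sg.dissociation_window
    a_mask = (t >= a0) & (t <= a1)
    d_mask = (t >= d0) & (t <= d1)
    if not a_mask.any() or not d_mask.any():
        raise ValueError("association and dissociation windows must contain samples")
    concs = sorted(sg.traces)
    rmax0 = max(max(np.max(tr) for tr in sg.traces.values()), 1e-9)

    # kd seed from the log-linear dissociation tail of the highest curve
    tr_hi = sg.traces[concs[-1]][d_mask]
    td = t[d_mask] - d0
    pos = tr_hi > 1e-12
    if pos.sum() >= 2:
        slope = np.polyfit(td[pos], np.log(tr_hi[pos]), 1)[0]
        kd0 = max(-slope, 1e-6)
    else:
        kd0 = 1e-3
    ka0 = kd0 / np.median(concs)

    def unpack(p):
        # clip log-parameters to keep exp finite during LM line searches
        q = np.clip(p, -60.0, 60.0)
        ka, kd, rmax = np.exp(q[:3])
        r0s = np.exp(q[3:])
        return ka, kd, rmax, r0s

    def residuals(p):
        ka, kd, rmax, r0s = unpack(p)
        res = []
        for i, c in enumerate(concs):
            tr = sg.traces[c]
            res.append(tr[a_mask] - association_model(t[a_mask] - a0, c, ka, kd, rmax))
            res.append(tr[d_mask] - dissociation_model(t[d_mask] - d0, r0s[i], kd))
        return np.concatenate(res)

    r0_seed = [max(sg.traces[c][d_mask][0], 1e-9) for c in concs]
    p0 = np.log([ka0, kd0, rmax0, *r0_seed])
    sol = least_squares(residuals, p0, method="lm", max_nfev=20000)
    ka, kd, rmax, _ = unpack(sol.x)

    flags = []
    if kd * (d1 - d0) < 0.01:
        flags.append("no_observable_decay")

    # standard errors on log-parameters -> relative errors, propagated
    m, n = sol.fun.size, sol.x.size
    if m > n:
        try:
            jtj_inv = np.linalg.inv(sol.jac.T @ sol.jac)
            s2 = 2.0 * sol.cost / (m - n)
            log_se = np.sqrt(np.clip(np.diag(jtj_inv) * s2, 0, None))
        except np.linalg.LinAlgError:
            log_se = np.full(n, np.inf)
    else:
        log_se = np.full(n, np.inf)
    if flags:
        log_se[:2] = np.inf  # unobservable decay: rate constants unconstrained
    se = {
        "ka": float(ka * log_se[0]),
        "kd": float(kd * log_se[1]),
        "Rmax": float(rmax * log_se[2]),
        "KD": float(kd / ka * np.hypot(log_se[0], log_se[1])),
    }
    return FitResult(
        {"ka": float(ka), "kd": float(kd), "Rmax": float(rmax), "KD": float(kd / ka)},
        se,
        float(np.linalg.norm(sol.fun)),
        bool(sol.success),
        flags,
    )


# ---------------------------------------------------------------------------
# DSF Boltzmann melt
# ---------------------------------------------------------------------------

def boltzmann_model(temp, fmin, fmax, tm, slope):
    return fmin + (fmax - fmin) / (1.0 + np.exp((tm - temp) / slope))


def fit_boltzmann_tm(temperatures, fluorescence) -> FitResult:
    """Boltzmann sigmoid melt fit; Tm is the transition midpoint (degC)."""
    temp = np.asarray(temperatures, dtype=float)
    fl = np.asarray(fluorescence, dtype=float)
    if temp.size < 8:
        raise ValueError("need at least 8 points spanning the transition")
    fmin0, fmax0 = fl.min(), fl.max()
    if fmax0 - fmin0 < 1e-12 * max(abs(fmax0), 1.0):
        return FitResult({}, {}, np.inf, converged=False, flags=["flat_curve"])
    tm0 = temp[np.argmin(np.abs(fl - (fmin0 + fmax0) / 2.0))]
    try:
        popt, pcov = curve_fit(
            boltzmann_model, temp, fl, p0=[fmin0, fmax0, tm0, 1.0], maxfev=20000
        )
    except RuntimeError:
        return FitResult({}, {}, np.inf, converged=False, flags=["optimizer_failed"])
    resid = fl - boltzmann_model(temp, *popt)
    names = ["Fmin", "Fmax", "Tm", "slope"]
    converged = temp.min() <= popt[2] <= temp.max()
    return FitResult(
        dict(zip(names, map(float, popt))),
        _stderr_from_cov(pcov, names),
        float(np.linalg.norm(resid)),
        converged,
        [] if converged else ["tm_outside_range"],
    )


# ---------------------------------------------------------------------------
# FP displacement
# ---------------------------------------------------------------------------

def fp_displacement_model(dose, top, bottom, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def fit_fp_displacement(ts: TitrationSeries, min_dynamic_range: float = 0.2) -> FitResult:
    """Four-parameter logistic displacement fit; Kdisp = IC50.

    Curves whose polarization drops by less than ``min_dynamic_range`` of
    the upper plateau are flagged non-displacing.
    """
    x, y = ts.concentrations, ts.responses
    top0, bottom0 = y.max(), y.min()
    span = top0 - bottom0
    if top0 != 0 and span / abs(top0) < min_dynamic_range:
        return FitResult(
            {"top": float(top0), "bottom": float(bottom0)},
            {},
            np.inf,
            converged=False,
            flags=["non_displacing"],
        )
    mid = (top0 + bottom0) / 2.0
    ic50_0 = x[np.argmin(np.abs(y - mid))]
    try:
        popt, pcov = curve_fit(
            fp_displacement_model, x, y, p0=[top0, bottom0, ic50_0, 1.0],
            bounds=([-np.inf, -np.inf, 1e-15, 0.1], [np.inf, np.inf, np.inf, 10.0]),
            maxfev=20000,
        )
    except RuntimeError:
        return FitResult({}, {}, np.inf, converged=False, flags=["optimizer_failed"])
    resid = y - fp_displacement_model(x, *popt)
    params = {
        "top": float(popt[0]),
        "bottom": float(popt[1]),
        "Kdisp": float(popt[2]),
        "hill": float(popt[3]),
    }
    return FitResult(
        params,
        _stderr_from_cov(pcov, ["top", "bottom", "Kdisp", "hill"]),
        float(np.linalg.norm(resid)),
        True,
    )


def cheng_prusoff_ki(ic50: float, probe_conc: float, probe_kd: float) -> float:
    """Optional post-hoc conversion of a displacement IC50 to Ki."""
    return ic50 / (1.0 + probe_conc / probe_kd)


# ---------------------------------------------------------------------------
# Selectivity matrix
# ---------------------------------------------------------------------------

def theoretical_rmax(immobilization_level: float, mw_analyte: float, mw_ligand: float) -> float:
    """SPR saturation response: surface capacity scaled by the analyte/ligand mass ratio."""
    return immobilization_level * mw_analyte / mw_ligand


def selectivity_matrix(
    responses: pd.DataFrame,
    rmax_theoretical: dict[tuple[str, str], float],
    clamp: tuple[float, float] = (0.0, 120.0),
) -> pd.DataFrame:
    """Normalized percent binding of each compound against each protein.

    ``responses`` is long-format (compound, protein, replicate, response) at
    a fixed dose; each cell is the replicate mean of
    100 * R_obs / R_max,theoretical, clamped to ``clamp`` with an
    ``over_range`` flag for super-stoichiometric binding.  Pairs without a
    theoretical Rmax are marked not computable (NaN).

    Returns a long DataFrame (compound, protein, percent_binding, over_range,
    computable); pivot on (compound, protein) for the matrix view.
    """
    required = {"compound", "protein", "response"}
    if not required <= set(responses.columns):
        raise ValueError(f"responses must carry columns {sorted(required)}")
    grouped = responses.groupby(["compound", "protein"], as_index=False)["response"].mean()
    rows = []
    for _, row in grouped.iterrows():
        key = (row["compound"], row["protein"])
        rmax = rmax_theoretical.get(key)
        if rmax is None or rmax <= 0:
            rows.append(
                {
                    "compound": key[0], "protein": key[1],
                    "percent_binding": np.nan, "over_range": False, "computable": False,
                }
            )
            continue
        pct = 100.0 * row["response"] / rmax
        rows.append(
            {
                "compound": key[0], "protein": key[1],
                "percent_binding": float(np.clip(pct, *clamp)),
                "over_range": bool(pct > clamp[1]),
                "computable": True,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Assay simulators (forward models + noise) for parameter-recovery studies
# ---------------------------------------------------------------------------

def dilution_series(top: float, fold: float = 3.0, n: int = 8) -> np.ndarray:
    """Descending-fold dilution series, returned in increasing order."""
    return np.array(sorted(top / fold**i for i in range(n)))


def simulate_assay(
    kind: str,
    true_params: dict[str, float],
    design: dict,
    noise_cv: float = 0.0,
    seed: int = 0,
):
    """Forward-simulate an assay from its closed-form model.

    ``kind``: one of steady_state | kinetic | dsf | fp.  Gaussian noise with
    coefficient of variation ``noise_cv`` (relative to the dynamic range) is
    added i.i.d.; deterministic per seed.
    """
    rng = np.random.default_rng(seed)

    def noisy(y):
        if noise_cv <= 0:
            return y
        scale = noise_cv * (np.max(np.abs(y)) if np.max(np.abs(y)) > 0 else 1.0)
        return y + rng.normal(0.0, scale, size=np.shape(y))

    if kind == "steady_state":
        conc = np.asarray(design["concentrations"], dtype=float)
        y = steady_state_model(conc, true_params["KD"], true_params["Rmax"])
        return TitrationSeries(conc, noisy(y), kind="spr_steady_state")

    if kind == "kinetic":
        t = np.asarray(design["time"], dtype=float)
        a0, a1 = design["association_window"]
        d0, d1 = design["dissociation_window"]
        ka, kd, rmax = true_params["ka"], true_params["kd"], true_params["Rmax"]
        traces = {}
        for c in design["concentrations"]:
            tr = np.zeros_like(t)
            a_mask = (t >= a0) & (t <= a1)
            tr[a_mask] = association_model(t[a_mask] - a0, c, ka, kd, rmax)
            r_end = association_model(a1 - a0, c, ka, kd, rmax)
            d_mask = t > a1
            tr[d_mask] = dissociation_model(t[d_mask] - d0, r_end, kd)
            traces[float(c)] = noisy(tr)
        return Sensorgram(t, traces, (a0, a1), (d0, d1))

    if kind == "dsf":
        temp = np.asarray(design["temperatures"], dtype=float)
        y = boltzmann_model(
            temp,
            true_params.get("Fmin", 0.0),
            true_params.get("Fmax", 1.0),
            true_params["Tm"],
            true_params.get("slope", 1.5),
        )
        return temp, noisy(y)

    if kind == "fp":
        dose = np.asarray(design["doses"], dtype=float)
        y = fp_displacement_model(
            dose,
            true_params.get("top", 200.0),
            true_params.get("bottom", 60.0),
            true_params["Kdisp"],
            true_params.get("hill", 1.0),
        )
        return TitrationSeries(dose, noisy(y), kind="fp")

    raise ValueError(f"unknown assay kind {kind!r}")
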