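"""Titration analysis: frame classification, tempered reweighting, pKa fits.

The λ trajectories are produced at a high fictitious temperature T_λ, so
the observed deprotonated/protonated count ratio r must be mapped back to
the physical temperature T before fitting: under adiabatic separation the
λ marginal is Boltzmann in the physical-temperature free energy at k_B T_λ,
hence r(T) = r(T_λ)^(T_λ/T).  The reweighted fractions across a pH grid are
then fit with the generalized Henderson–Hasselbalch curve

    f(pH) = 1 / (1 + 10^(n (pKa − pH)))

(Hill coefficient n), or, for a pair of interacting sites, with the
two-site stepwise-ionization-constant model for the mean proton count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import KB, LN10

__all__ = [
    "TitrationPoint",
    "PkaFit",
    "classify_frames",
    "reweight_fraction",
    "his_deprot_fraction",
    "free_energy_profile",
    "ionization_energy_series",
    "fit_hh",
    "fit_coupled",
    "prediction_metrics",
    "pka_from_trajectories",
]

#: λ classification thresholds: protonated below, deprotonated above.
LAMBDA_LO = 0.2
LAMBDA_HI = 0.8

#: Fraction of frames discarded as equilibration before counting.
BURN_IN_FRACTION = 0.1

#: Clipping applied to fractions before fitting (avoids log-degenerate ends).
FRACTION_EPS = 1e-6


@dataclass
class TitrationPoint:
    """Per-pH deprotonation statistics for one site."""

    pH: float
    fraction: float  # reweighted deprotonated fraction at T
    replicate_mean: float = math.nan
    replicate_std: float = math.nan
    mixed_fraction: float = 0.0
    n_prot: int = 0
    n_deprot: int = 0
    n_mixed: int = 0
    one_sided: bool = False  # a zero count forced the fraction to 0 or 1
    sigma: float = math.nan  # per-point fit weight (std of `fraction`)

    def __post_init__(self) -> None:
        for name in ("fraction", "mixed_fraction"):
            v = getattr(self, name)
            if not (math.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if min(self.n_prot, self.n_deprot, self.n_mixed) < 0:
            raise ValueError("frame counts must be >= 0")


@dataclass
class PkaFit:
    """Result of a titration-curve fit."""

    pKa: float
    hill_n: float = 1.0
    pKa2: Optional[float] = None  # second constant of a coupled fit
    residual_norm: float = math.nan
    converged: bool = True
    flags: List[str] = field(default_factory=list)


def classify_frames(lambda_series, lo: float = LAMBDA_LO,
                    hi: float = LAMBDA_HI) -> Tuple[int, int, int]:
    """Count (protonated, deprotonated, mixed) frames of a λ series.

    A frame is protonated if λ < lo, deprotonated if λ > hi, mixed
    otherwise; the three counts partition the series.
    """
    lam = np.asarray(lambda_series, dtype=float)
    if lam.size == 0:
        raise ValueError("cannot classify an empty λ series")
    if not lo < hi:
        raise ValueError("need lo < hi classification thresholds")
    n_prot = int(np.count_nonzero(lam < lo))
    n_deprot = int(np.count_nonzero(lam > hi))
    return n_prot, n_deprot, lam.size - n_prot - n_deprot


def _tempered_fraction(n_prot: float, n_deprot: float, T_lambda: float,
                       T: float) -> Tuple[float, bool]:
    if T_lambda <= 0 or T <= 0:
        raise ValueError("temperatures must be > 0")
    if n_prot < 0 or n_deprot < 0:
        raise ValueError("counts must be >= 0")
    if n_prot + n_deprot == 0:
        raise ValueError("no classified frames: both counts are zero")
    if n_deprot == 0:
        return 0.0, True
    if n_prot == 0:
        return 1.0, True
    # work in log space: exponent T_lambda/T can overflow the plain power
    log_r = (T_lambda / T) * (math.log(n_deprot) - math.log(n_prot))
    if log_r > 0:
        return 1.0 / (1.0 + math.exp(-log_r)), False
    e = math.exp(log_r)
    return e / (1.0 + e), False


def reweight_fraction(n_prot: int, n_deprot: int, T_lambda: float,
                      T: float) -> Tuple[float, bool]:
    """Deprotonated fraction at T from counts observed at T_λ.

    The count ratio r = n_deprot/n_prot observed at T_λ maps to
    r^(T_λ/T) at T; returns (fraction, one_sided_flag) where the flag marks
    a zero count (fraction pinned to 0 or 1 without reweighting support).
    """
    return _tempered_fraction(n_prot, n_deprot, T_lambda, T)


def his_deprot_fraction(n_p: int, n_c: int, n_delta: int, T_lambda: float,
                        T: float) -> Tuple[float, bool]:
    """Histidine deprotonated fraction from multisite counts.

    The two neutral tautomer counts are pooled into the deprotonated class
    and reweighted against the protonated-state count exactly as in the
    single-site case.
    """
    return _tempered_fraction(n_p, n_c + n_delta, T_lambda, T)


def free_energy_profile(lambda_series, T_lambda: float, n_bins: int = 50,
                        lam_range: Tuple[float, float] = (-0.1, 1.1)):
    """Binned free energy F(λ) = −k_B T_λ ln P̂(λ), shifted so min F = 0.

    Returns (bin_centers, F) with empty bins set to NaN (undefined, never
    zero-filled).
    """
    lam = np.asarray(lambda_series, dtype=float)
    if lam.size == 0:
        raise ValueError("cannot profile an empty λ series")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    counts, edges = np.histogram(lam, bins=n_bins, range=lam_range)
    centers = 0.5 * (edges[:-1] + edges[1:])
    F = np.full(n_bins, np.nan)
    pop = counts > 0
    F[pop] = -KB * T_lambda * np.log(counts[pop] / lam.size)
    F -= np.nanmin(F)
    return centers, F


def ionization_energy_series(lambda_series, T: float, stride: int = 1,
                             lo: float = LAMBDA_LO, hi: float = LAMBDA_HI):
    """Cumulative ionization free energy −k_B T ln(n_deprot/n_prot) vs frame.

    Checkpoints where either cumulative count is still zero are NaN
    (undefined), matching the convention that nonfinite ionization energies
    are excluded rather than clamped.  Negative values mean deprotonation
    dominates.
    """
    lam = np.asarray(lambda_series, dtype=float)
    if lam.size < stride:
        raise ValueError("series shorter than one stride")
    cum_p = np.cumsum(lam < lo)
    cum_d = np.cumsum(lam > hi)
    idx = np.arange(stride - 1, lam.size, stride)
    out = np.full(idx.size, np.nan)
    ok = (cum_p[idx] > 0) & (cum_d[idx] > 0)
    out[ok] = -KB * T * np.log(cum_d[idx][ok] / cum_p[idx][ok])
    return idx + 1, out


# ---------------------------------------------------------------------------
# Titration-curve fits
# ---------------------------------------------------------------------------


def _hh(ph, pka, n):
    return 1.0 / (1.0 + 10.0 ** (n * (pka - ph)))


def fit_hh(points: Sequence[TitrationPoint]) -> PkaFit:
    """Weighted least-squares fit of the generalized Henderson–Hasselbalch curve.

    Weights are inverse replicate variances where available (with a floor),
    otherwise uniform; fractions are clipped away from exactly 0/1 first.
    The Hill coefficient is bounded to (0, 4].
    """
    pts = sorted(points, key=lambda p: p.pH)
    ph = np.array([p.pH for p in pts])
    f = np.clip(np.array([p.fraction for p in pts]),
                FRACTION_EPS, 1.0 - FRACTION_EPS)
    flags: List[str] = []
    if len(pts) < 3:
        flags.append("too_few_points")
    if np.all(f < 0.5) or np.all(f > 0.5):
        flags.append("low_confidence_no_midpoint")
    raw = np.array([p.fraction for p in pts])
    if np.all(raw <= FRACTION_EPS) or np.all(raw >= 1 - FRACTION_EPS):
        return PkaFit(pKa=math.nan, hill_n=math.nan, converged=False,
                      flags=flags + ["degenerate_no_fit"])
    # point weights: an explicit per-point sigma (e.g. the counting-noise
    # model used by the trajectory pipeline) takes precedence, then the
    # cross-replicate standard deviation, then uniform weights
    sig = np.array([p.sigma for p in pts])
    if not np.all(np.isfinite(sig)):
        sig = np.array([p.replicate_std for p in pts])
    if np.all(np.isfinite(sig)) and np.all(sig >= 0):
        sigma = np.maximum(sig, 0.01)
    else:
        sigma = np.ones_like(f)
    p0_pka = ph[int(np.argmin(np.abs(f - 0.5)))]
    try:
        popt, _ = curve_fit(
            _hh, ph, f, p0=[p0_pka, 1.0], sigma=sigma,
            bounds=([ph.min() - 20.0, 1e-6], [ph.max() + 20.0, 4.0]),
            maxfev=10000,
        )
    except RuntimeError:
        return PkaFit(pKa=math.nan, hill_n=math.nan, converged=False,
                      flags=flags + ["fit_failed"])
    resid = f - _hh(ph, *popt)
    return PkaFit(pKa=float(popt[0]), hill_n=float(popt[1]),
                  residual_norm=float(np.linalg.norm(resid)),
                  converged=True, flags=flags)


def _fit_hh_logit(ph, logit_f, sigma_l) -> PkaFit:
    """Hill-model fit in its logit parameterization.

    The generalized Henderson–Hasselbalch curve is exactly equivalent to
    logit(f) = n·ln10·(pH − pKa), a straight line; the log count-ratio
    noise of a tempered trajectory is approximately Gaussian on this scale
    (it is multiplicative and heavy-tailed in fraction space), so the
    weighted linear regression here is the variance-stable way to fit the
    same model to counting-limited data.
    """
    ph = np.asarray(ph, dtype=float)
    y = np.asarray(logit_f, dtype=float)
    w = 1.0 / np.maximum(np.asarray(sigma_l, dtype=float), 1e-6) ** 2
    if ph.size < 3:
        return PkaFit(pKa=math.nan, hill_n=math.nan, converged=False,
                      flags=["too_few_points"])
    sw = w.sum()
    mx = (w * ph).sum() / sw
    my = (w * y).sum() / sw
    sxx = (w * (ph - mx) ** 2).sum()
    if sxx <= 0:
        return PkaFit(pKa=math.nan, hill_n=math.nan, converged=False,
                      flags=["degenerate_grid"])
    b = (w * (ph - mx) * (y - my)).sum() / sxx
    a = my - b * mx
    flags: List[str] = []
    if b <= 0:
        return PkaFit(pKa=math.nan, hill_n=math.nan, converged=False,
                      flags=["non_titrating_no_fit"])
    n = b / LN10
    if n > 4.0:
        n = 4.0
        flags.append("hill_clamped")
    resid = (y - (a + b * ph)) * np.sqrt(w)
    return PkaFit(pKa=float(-a / b), hill_n=float(n),
                  residual_norm=float(np.linalg.norm(resid)),
                  converged=True, flags=flags)


def _coupled_protons(ph, pka1, pka2):
    """Mean bound-proton count ⟨P⟩ of the two-site stepwise model."""
    x = 10.0 ** (-np.asarray(ph, dtype=float))
    k1 = 10.0 ** (-pka1)
    k2 = 10.0 ** (-pka2)
    return (2.0 * x ** 2 + k1 * x) / (x ** 2 + k1 * x + k1 * k2)


def fit_coupled(points_site1: Sequence[TitrationPoint],
                points_site2: Sequence[TitrationPoint]) -> PkaFit:
    """Coupled two-site titration fit via stepwise ionization constants.

    ⟨P⟩(pH) = (2x² + K₁x) / (x² + K₁x + K₁K₂), x = 10^(−pH); the data are
    the summed protonated fractions of the two sites on a shared pH grid.
    Returns the ordered pair (pKa, pKa2) with pKa ≤ pKa2.
    """
    p1 = sorted(points_site1, key=lambda p: p.pH)
    p2 = sorted(points_site2, key=lambda p: p.pH)
    ph1 = np.array([p.pH for p in p1])
    ph2 = np.array([p.pH for p in p2])
    if ph1.shape != ph2.shape or not np.allclose(ph1, ph2):
        raise ValueError("coupled fit requires a shared pH grid")
    mean_protons = (1.0 - np.array([p.fraction for p in p1])) + \
                   (1.0 - np.array([p.fraction for p in p2]))
    guess = [ph1[int(np.argmin(np.abs(mean_protons - 1.5)))],
             ph1[int(np.argmin(np.abs(mean_protons - 0.5)))]]
    popt, _ = curve_fit(_coupled_protons, ph1, mean_protons,
                        p0=guess, maxfev=20000)
    lo, hi = sorted(map(float, popt))
    resid = mean_protons - _coupled_protons(ph1, *popt)
    return PkaFit(pKa=lo, pKa2=hi, hill_n=1.0,
                  residual_norm=float(np.linalg.norm(resid)))


def prediction_metrics(predicted, experimental) -> Dict[str, float]:
    """MUE, RMSE and Pearson r of predicted vs experimental pKa values."""
    pred = np.asarray(predicted, dtype=float)
    exp = np.asarray(experimental, dtype=float)
    if pred.shape != exp.shape:
        raise ValueError("predicted and experimental lengths differ")
    if pred.size < 2:
        raise ValueError("need at least 2 pairs")
    d = pred - exp
    mue = float(np.mean(np.abs(d)))
    rmse = float(np.sqrt(np.mean(d ** 2)))
    if np.std(pred) == 0.0 or np.std(exp) == 0.0:
        return {"MUE": mue, "RMSE": rmse, "pearson_r": math.nan,
                "r_defined": False}
    r = float(np.corrcoef(pred, exp)[0, 1])
    return {"MUE": mue, "RMSE": rmse, "pearson_r": r, "r_defined": True}


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def basin_visits(lambda_series, lo: float = LAMBDA_LO,
                 hi: float = LAMBDA_HI) -> Tuple[int, int]:
    """Number of maximal basin visits (protonated, deprotonated).

    Mixed frames are transparent: a visit ends only when the series reaches
    the opposite basin.  Visit counts drive the counting-noise model of the
    reweighted fraction (few barrier crossings = unreliable ratio).
    """
    lam = np.asarray(lambda_series, dtype=float)
    labels = np.where(lam < lo, 0, np.where(lam > hi, 1, -1))
    labels = labels[labels >= 0]
    if labels.size == 0:
        return 0, 0
    switches = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[labels[0]], labels[switches + 1]])
    v_p = int(np.count_nonzero(starts == 0))
    v_d = int(np.count_nonzero(starts == 1))
    return v_p, v_d


def _site_counts(traj, site_id: str, burn_in: float):
    """Classified frame counts and basin-visit counts for one site."""
    cols = traj.site_columns(site_id)
    n0 = int(burn_in * traj.lam.shape[0])
    if len(cols) == 1:
        lam = traj.lambda_series(cols[0])[n0:]
        return classify_frames(lam), basin_visits(lam), False
    # multisite His: base protonation read off the protonated-state λ,
    # tautomer identities off the two neutral λs
    lam_p = traj.lambda_series(cols[0])[n0:]
    lam_c = traj.lambda_series(cols[1])[n0:]
    lam_d = traj.lambda_series(cols[2])[n0:]
    n_p = int(np.count_nonzero(lam_p > LAMBDA_HI))
    n_c = int(np.count_nonzero(lam_c > LAMBDA_HI))
    n_dl = int(np.count_nonzero(lam_d > LAMBDA_HI))
    n_mixed = lam_p.size - n_p - n_c - n_dl
    if n_mixed < 0:  # overlapping assignments count as mixed, not double
        n_mixed = 0
    # alternations of the base protonation state: deprotonated = λ_p low
    v_d, v_p = basin_visits(lam_p)
    return (n_p, n_c, n_dl, n_mixed), (v_p, v_d), True


def titration_table(trajs, site_id: str, T: float,
                    burn_in: float = BURN_IN_FRACTION) -> pd.DataFrame:
    """Per-(pH, replicate) reweighted deprotonation fractions for one site."""
    rows = []
    for traj in trajs:
        t_lambda = float(np.max(traj.metadata["T_lambda"]))
        counts, visits, is_his = _site_counts(traj, site_id, burn_in)
        if is_his:
            n_p, n_c, n_dl, n_mixed = counts
            total = n_p + n_c + n_dl + n_mixed
            if n_p + n_c + n_dl == 0:
                frac, flag = math.nan, True
            else:
                frac, flag = his_deprot_fraction(n_p, n_c, n_dl, t_lambda, T)
            n_prot, n_deprot = n_p, n_c + n_dl
        else:
            n_prot, n_deprot, n_mixed = counts
            total = n_prot + n_deprot + n_mixed
            if n_prot + n_deprot == 0:
                frac, flag = math.nan, True
            else:
                frac, flag = reweight_fraction(n_prot, n_deprot, t_lambda, T)
        v_p, v_d = visits
        # counting-noise model: the log count ratio carries ~1/sqrt(visits)
        # noise per basin, amplified by T_lambda/T through the reweighting.
        # logit_f is the reweighted log-ratio (the logit of `fraction`).
        if flag or math.isnan(frac) or min(v_p, v_d) < 1 or \
                min(n_prot, n_deprot) < 1:
            logit_f = math.nan
            sigma_l = math.nan
            sigma = 1.0
        else:
            logit_f = (t_lambda / T) * math.log(n_deprot / n_prot)
            sigma_l = (t_lambda / T) * math.sqrt(1.0 / v_p + 1.0 / v_d)
            sigma = max(0.01, frac * (1.0 - frac) * sigma_l)
        rows.append({
            "pH": float(traj.metadata["pH"]),
            "seed": int(traj.metadata["seed"]),
            "replicate": int(traj.metadata.get("replicate", traj.metadata["seed"])),
            "site": site_id,
            "fraction": frac,
            "mixed_fraction": n_mixed / total if total else math.nan,
            "n_prot": n_prot,
            "n_deprot": n_deprot,
            "n_mixed": n_mixed,
            "v_prot": v_p,
            "v_deprot": v_d,
            "sigma": sigma,
            "logit_f": logit_f,
            "sigma_logit": sigma_l,
            "one_sided": flag,
        })
    return pd.DataFrame(rows).sort_values(["pH", "seed"]).reset_index(drop=True)


def pka_from_trajectories(trajs, site_id: str, T: float = 300.0,
                          burn_in: float = BURN_IN_FRACTION):
    """Full pipeline: classify → reweight → per-replicate HH fit → mean ± std.

    `trajs` holds every (pH, replicate) trajectory of one titration scan.
    Returns (pKa_mean, pKa_std, table) where `table` is the per-pH titration
    DataFrame (replicate-aggregated) and the per-replicate fits are attached
    under table.attrs["replicate_fits"].
    """
    df = titration_table(trajs, site_id, T, burn_in)
    if df["pH"].nunique() < 3:
        raise ValueError("need at least 3 pH values for a titration fit")
    fits: List[PkaFit] = []
    for _rep, grp in df.groupby("replicate"):
        ok = grp[np.isfinite(grp["logit_f"])]
        if len(ok) >= 3:
            fits.append(_fit_hh_logit(ok["pH"], ok["logit_f"],
                                      ok["sigma_logit"]))
    good = [f.pKa for f in fits if f.converged and math.isfinite(f.pKa)]
    agg = df.groupby("pH").agg(
        fraction=("fraction", "mean"),
        fraction_std=("fraction", "std"),
        mixed_fraction=("mixed_fraction", "mean"),
        n_prot=("n_prot", "sum"),
        n_deprot=("n_deprot", "sum"),
        n_mixed=("n_mixed", "sum"),
    ).reset_index()
    agg.attrs["replicate_fits"] = fits
    if not good:
        agg.attrs["flags"] = ["no_converged_fit"]
        return math.nan, math.nan, agg
    pka_mean = float(np.mean(good))
    pka_std = float(np.std(good, ddof=1)) if len(good) > 1 else 0.0
    agg.attrs["flags"] = sorted({fl for f in fits for fl in f.flags})
    return pka_mean, pka_std, agg
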