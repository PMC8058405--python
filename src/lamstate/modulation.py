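"""Sound modulation indices, running/VIP effects, and the additivity test.

The sound modulation index contrasts mean evoked and spontaneous firing::

    MI = (E - S) / (E + S)

computed per unit in each of four conditions (sitting/running x laser
off/on): E is the mean onset-window rate on white-noise trials of that
condition and S the mean rate on the interleaved blanks of the same
condition. Only units with a significant sound-evoked *increase* (sitting
laser-off) enter the MI analyses, so MI(sitting, laser-off) lies in [0, 1];
under running or laser the MI can fall as low as -1.

The four condition MIs yield the effect decomposition::

    running effect     = MI(run, off) - MI(sit, off)        range [-2, 2]
    VIP effect         = MI(sit, on)  - MI(sit, off)        range [-2, 2]
    predicted combined = running effect + VIP effect        range [-4, 4]
    observed combined  = MI(run, on)  - MI(sit, off)

If running and VIP activation act through independent mechanisms the
observed combined effect should match the predicted (arithmetic-sum)
effect; a sub-additive interaction instead compresses the observed values
(regression slope < 1). The additivity test reports the rank correlation
and the observed~predicted least-squares fit across units.

Because running trials are rare (~13% of trials), sitting-vs-running MI
comparisons are repeated on 100 random sitting-trial subsets matched in
trial count to the running trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .responses import (
    ConditionKey,
    ONSET_WINDOW,
    condition_trials,
    psth,
    significant_evoked,
    trial_rates,
)
from .session import Session, Unit

__all__ = [
    "AdditivityResult",
    "SubsampleResult",
    "additivity_test",
    "compute_modulation",
    "condition_mi",
    "effects",
    "laser_effect_norm",
    "matched_subsample_mi",
    "rate_additivity_test",
    "sound_mi",
]

#: minimum trials per (WN, blank) selection for a condition MI to be defined;
#: mirrors the 7-running-trial session floor as a symmetric evidence bar.
MIN_TRIALS_PER_CONDITION = 7


def sound_mi(evoked_hz: float, spont_hz: float) -> float:
    """(E - S) / (E + S); NaN when both rates are zero (undefined)."""
    if evoked_hz < 0 or spont_hz < 0:
        raise ValueError("rates must be nonnegative")
    denom = evoked_hz + spont_hz
    if denom == 0:
        return float("nan")
    return (evoked_hz - spont_hz) / denom


def condition_mi(
    unit: Unit,
    trials: pd.DataFrame,
    state: str,
    laser: str,
    stim_dur_s: float = 0.6,
    min_trials: int = MIN_TRIALS_PER_CONDITION,
) -> float:
    """Sound MI of one unit in one (state, laser) condition; NaN if too few trials.

    Evoked rate is the onset-window (0-100 ms) mean over WN trials of the
    condition; spontaneous rate is the full stimulus-window mean over the
    condition's blanks.
    """
    wn = condition_trials(trials, ConditionKey(state, laser, "WN"))
    blank = condition_trials(trials, ConditionKey(state, laser, "blank"))
    if len(wn) < min_trials or len(blank) < min_trials:
        return float("nan")
    evoked = float(np.mean(trial_rates(unit, wn, ONSET_WINDOW)))
    spont = float(np.mean(trial_rates(unit, blank, (0.0, stim_dur_s))))
    return sound_mi(evoked, spont)


def effects(
    mi_sit_off: float, mi_run_off: float, mi_sit_on: float, mi_run_on: float
) -> tuple[float, float, float, float]:
    """(running effect, VIP effect, predicted combined, observed combined).

    Any effect whose inputs are undefined (NaN) is itself NaN.
    """
    running_effect = mi_run_off - mi_sit_off
    vip_effect = mi_sit_on - mi_sit_off
    predicted = running_effect + vip_effect
    observed = mi_run_on - mi_sit_off
    return running_effect, vip_effect, predicted, observed


def laser_effect_norm(
    unit: Unit,
    trials: pd.DataFrame,
    stim_dur_s: float = 0.6,
    min_trials: int = 2,
) -> tuple[float, float]:
    """Laser-on minus laser-off rate, normalized to the peak laser-off rate.

    Computed on sitting trials only; evoked uses the onset window on WN
    trials, spontaneous uses the full stimulus window on blanks. The
    normalizer is the peak of the smoothed laser-off WN PSTH, so the effect
    is invariant to overall rate scaling. Returns (NaN, NaN) on a zero peak.
    """
    sel = {
        (stim, laser): condition_trials(trials, ConditionKey("sitting", laser, stim))
        for stim in ("WN", "blank")
        for laser in ("off", "on")
    }
    if any(len(v) < min_trials for v in sel.values()):
        return float("nan"), float("nan")
    _, rate = psth(unit, sel[("WN", "off")], window=(0.0, stim_dur_s + 0.1),
                   smooth_bins=3)
    peak = float(rate.max())
    if peak <= 0:
        return float("nan"), float("nan")
    ev_on = float(np.mean(trial_rates(unit, sel[("WN", "on")], ONSET_WINDOW)))
    ev_off = float(np.mean(trial_rates(unit, sel[("WN", "off")], ONSET_WINDOW)))
    sp_on = float(np.mean(trial_rates(unit, sel[("blank", "on")], (0.0, stim_dur_s))))
    sp_off = float(np.mean(trial_rates(unit, sel[("blank", "off")], (0.0, stim_dur_s))))
    return (ev_on - ev_off) / peak, (sp_on - sp_off) / peak


def compute_modulation(
    session: Session,
    min_trials: int = MIN_TRIALS_PER_CONDITION,
    require_sig: bool = True,
) -> pd.DataFrame:
    """Per-unit modulation table: four condition MIs and derived effects.

    Units failing the increase-only responsiveness test (or with too few
    trials in a condition) carry NaN in the affected columns; exclusion is
    pairwise downstream, never imputed.
    """
    trials = session.trials
    stim_dur = session.meta.stim_dur_s
    rows = []
    for u in session.units:
        try:
            sig, p_sig = significant_evoked(u, trials)
        except ValueError:
            sig, p_sig = False, float("nan")
        if sig or not require_sig:
            mis = {
                (state, laser): condition_mi(
                    u, trials, state, laser, stim_dur, min_trials
                )
                for state in ("sitting", "running")
                for laser in ("off", "on")
            }
        else:
            mis = {k: float("nan") for k in
                   [(s, l) for s in ("sitting", "running") for l in ("off", "on")]}
        run_eff, vip_eff, pred, obs = effects(
            mis[("sitting", "off")],
            mis[("running", "off")],
            mis[("sitting", "on")],
            mis[("running", "on")],
        )
        ev_norm, sp_norm = laser_effect_norm(u, trials, stim_dur)
        rows.append(
            {
                "unit_id": u.unit_id,
                "layer": u.layer,
                "cell_class": u.cell_class,
                "sig_increase": sig,
                "p_sig": p_sig,
                "mi_sit_off": mis[("sitting", "off")],
                "mi_run_off": mis[("running", "off")],
                "mi_sit_on": mis[("sitting", "on")],
                "mi_run_on": mis[("running", "on")],
                "running_effect": run_eff,
                "vip_effect": vip_eff,
                "predicted_combined": pred,
                "observed_combined": obs,
                "laser_effect_evoked_norm": ev_norm,
                "laser_effect_spont_norm": sp_norm,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AdditivityResult:
    """Observed-vs-predicted combined-effect comparison across units."""

    rho: float  # Spearman rank correlation
    p: float
    slope: float
    intercept: float
    r2: float
    n: int
    r2_running_only: float
    r2_vip_only: float


def additivity_test(modulation: pd.DataFrame) -> AdditivityResult:
    """Rank correlation and OLS fit of observed vs predicted combined effects.

    Also fits the two single-predictor comparison models (observed ~ running
    effect alone, observed ~ VIP effect alone) whose r^2 should fall below
    the combined predictor's if the effects genuinely sum.
    """
    df = modulation.dropna(subset=["predicted_combined", "observed_combined"])
    if len(df) < 3:
        raise ValueError(
            f"additivity test needs >=3 units with both effects, have {len(df)}"
        )
    pred = df["predicted_combined"].to_numpy(float)
    obs = df["observed_combined"].to_numpy(float)
    rho, p = stats.spearmanr(pred, obs)
    fit = stats.linregress(pred, obs)

    def _r2(x: np.ndarray) -> float:
        ok = np.isfinite(x) & np.isfinite(obs)
        if ok.sum() < 3 or np.ptp(x[ok]) == 0:
            return float("nan")
        return float(stats.linregress(x[ok], obs[ok]).rvalue ** 2)

    return AdditivityResult(
        rho=float(rho),
        p=float(p),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n=len(df),
        r2_running_only=_r2(df["running_effect"].to_numpy(float)),
        r2_vip_only=_r2(df["vip_effect"].to_numpy(float)),
    )


def rate_additivity_test(
    session: Session,
    min_trials: int = MIN_TRIALS_PER_CONDITION,
) -> dict[str, AdditivityResult]:
    """Additivity test on raw (non-normalized) firing-rate changes.

    Repeats the observed-vs-predicted comparison on evoked (onset-window,
    WN trials) and spontaneous (blank-window) rate changes instead of MI
    differences, confirming that the additivity conclusion does not hinge
    on the bounded MI normalization. Returns results keyed by
    ``"evoked"`` and ``"spont"``.
    """
    trials = session.trials
    stim_dur = session.meta.stim_dur_s
    windows = {
        "evoked": ("WN", ONSET_WINDOW),
        "spont": ("blank", (0.0, stim_dur)),
    }
    out = {}
    for name, (stim, window) in windows.items():
        rows = []
        sels = {
            (state, laser): condition_trials(trials, ConditionKey(state, laser, stim))
            for state in ("sitting", "running")
            for laser in ("off", "on")
        }
        if any(len(v) < min_trials for v in sels.values()):
            raise ValueError(f"too few trials for raw-rate additivity ({name})")
        for u in session.units:
            r = {
                k: float(np.mean(trial_rates(u, sel, window)))
                for k, sel in sels.items()
            }
            run_eff = r[("running", "off")] - r[("sitting", "off")]
            laser_eff = r[("sitting", "on")] - r[("sitting", "off")]
            rows.append(
                {
                    "unit_id": u.unit_id,
                    "running_effect": run_eff,
                    "vip_effect": laser_eff,
                    "predicted_combined": run_eff + laser_eff,
                    "observed_combined": r[("running", "on")] - r[("sitting", "off")],
                }
            )
        out[name] = additivity_test(pd.DataFrame(rows))
    return out


@dataclass
class SubsampleResult:
    """Matched-trial-count sitting-MI subsampling outcome."""

    n_repeats: int
    n_running_wn: int
    n_running_blank: int
    sitting_means: np.ndarray  # population mean sitting MI per repeat
    p_values: np.ndarray  # paired signed-rank p per repeat
    running_mean: float
    mean: float = field(init=False)
    sem: float = field(init=False)
    range: tuple[float, float] = field(init=False)
    mean_p: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean = float(np.mean(self.sitting_means))
        self.sem = float(
            np.std(self.sitting_means, ddof=1) / np.sqrt(len(self.sitting_means))
        ) if len(self.sitting_means) > 1 else 0.0
        self.range = (float(np.min(self.sitting_means)),
                      float(np.max(self.sitting_means)))
        self.mean_p = float(np.mean(self.p_values))


def matched_subsample_mi(
    session: Session,
    modulation: pd.DataFrame,
    n_repeats: int = 100,
    seed: int | np.random.Generator = 0,
    min_trials: int = 2,
) -> SubsampleResult:
    """Sitting-vs-running MI comparison at matched trial counts (laser-off).

    Per repeat, draws without replacement as many sitting WN (and blank)
    laser-off trials as there are running ones, recomputes each responsive
    unit's sitting MI on the subset, and runs a paired signed-rank test
    against the running MI across units. The subsampling RNG is independent
    of any generator RNG.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    trials = session.trials
    stim_dur = session.meta.stim_dur_s
    run_wn = condition_trials(trials, ConditionKey("running", "off", "WN"))
    run_blank = condition_trials(trials, ConditionKey("running", "off", "blank"))
    sit_wn = condition_trials(trials, ConditionKey("sitting", "off", "WN"))
    sit_blank = condition_trials(trials, ConditionKey("sitting", "off", "blank"))
    if len(sit_wn) < len(run_wn) or len(sit_blank) < len(run_blank):
        raise ValueError("fewer sitting than running trials; cannot match counts")

    keep = modulation[modulation["sig_increase"] & modulation["mi_run_off"].notna()]
    units = [session.unit(uid) for uid in keep["unit_id"]]
    running_mi = keep["mi_run_off"].to_numpy(float)
    if len(units) == 0:
        raise ValueError("no responsive units with a defined running MI")

    sitting_means = np.empty(n_repeats)
    p_values = np.empty(n_repeats)
    for rep in range(n_repeats):
        wn_idx = rng.choice(len(sit_wn), size=len(run_wn), replace=False)
        bl_idx = rng.choice(len(sit_blank), size=len(run_blank), replace=False)
        sub_wn = sit_wn.iloc[np.sort(wn_idx)]
        sub_blank = sit_blank.iloc[np.sort(bl_idx)]
        mis = np.array(
            [
                sound_mi(
                    float(np.mean(trial_rates(u, sub_wn, ONSET_WINDOW))),
                    float(np.mean(trial_rates(u, sub_blank, (0.0, stim_dur)))),
                )
                for u in units
            ]
        )
        ok = np.isfinite(mis) & np.isfinite(running_mi)
        sitting_means[rep] = np.nanmean(mis)
        diff = mis[ok] - running_mi[ok]
        if np.allclose(diff, 0):
            p_values[rep] = 1.0
        else:
            p_values[rep] = float(stats.wilcoxon(mis[ok], running_mi[ok]).pvalue)
    return SubsampleResult(
        n_repeats=n_repeats,
        n_running_wn=len(run_wn),
        n_running_blank=len(run_blank),
        sitting_means=sitting_means,
        p_values=p_values,
        running_mean=float(np.nanmean(running_mi)),
    )
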