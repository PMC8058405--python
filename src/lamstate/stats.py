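"""Group statistics, effect sizes, and end-to-end pipeline orchestration.

All comparisons are non-parametric: two-sided Wilcoxon signed-rank for
within-group (paired) contrasts, two-sided Wilcoxon rank-sum for
between-group contrasts, and Kruskal-Wallis for multi-group (laminar)
comparisons with Bonferroni-corrected rank-sum post-hoc tests. Effect
sizes use r = z / sqrt(N), where z is the normal-scale Wilcoxon statistic
and N the total number of cases (twice the sample size for paired tests).

:func:`run_pipeline` chains the full analysis on one session directory:
trial classification -> CSD/laminar assignment -> cell classification ->
response metrics -> modulation/additivity -> distance-correlation sweep ->
laminar group statistics, and emits a machine-readable report in which
every number carries its stage parameters and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import behavior, csd as csd_mod, modulation as mod_mod, timescale
from .responses import response_table
from .session import Session, read_session
from .waveforms import classify_unit, waveform_features

__all__ = [
    "GroupComparison",
    "PipelineConfig",
    "effect_size_r",
    "grouped_kruskal",
    "layer_group_test",
    "rank_sum",
    "run_pipeline",
    "signed_rank",
]

log = logging.getLogger("lamstate")


def effect_size_r(z: float, n_cases: int) -> float:
    """r = z / sqrt(N); N is doubled by the caller for paired comparisons."""
    if n_cases <= 0:
        raise ValueError("n_cases must be positive")
    return float(z) / float(np.sqrt(n_cases))


def signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Paired two-sided signed-rank test: (z, p, effect size r).

    Uses the normal approximation with continuity correction so a z-scale
    statistic exists; N = 2 * number of pairs for the effect size.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if np.allclose(x, y):
        return 0.0, 1.0, 0.0
    res = sps.wilcoxon(x, y, correction=True, method="approx")
    z = float(res.zstatistic)
    return z, float(res.pvalue), effect_size_r(z, 2 * len(x))


def rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Independent two-sided rank-sum test: (z, p, effect size r)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    res = sps.ranksums(x, y)
    z = float(res.statistic)
    return z, float(res.pvalue), effect_size_r(z, len(x) + len(y))


@dataclass
class GroupComparison:
    """Outcome of a multi-group Kruskal-Wallis with rank-sum post hocs."""

    test: str
    statistic: float  # chi-square scale
    df: int
    p: float
    n_cases: int
    effect_size_r: float | None = None
    post_hoc: list[dict] = field(default_factory=list)


def layer_group_test(
    values_by_group: dict[str, np.ndarray],
    alpha: float = 0.05,
    post_hoc: bool = True,
) -> GroupComparison:
    """Kruskal-Wallis across layers (or any grouping) + Bonferroni post hocs.

    Groups with no finite values are dropped; at least two nonempty groups
    are required. Post-hoc pairwise rank-sum tests run only when the
    omnibus p falls below ``alpha`` and use the familywise alpha divided by
    the exact number of pairs.
    """
    groups = {
        k: np.asarray(v, float)[np.isfinite(np.asarray(v, float))]
        for k, v in values_by_group.items()
    }
    groups = {k: v for k, v in groups.items() if v.size > 0}
    if len(groups) < 2:
        raise ValueError(f"need >=2 nonempty groups, have {len(groups)}")
    names = sorted(groups)
    stat, p = sps.kruskal(*[groups[k] for k in names])
    n = int(sum(v.size for v in groups.values()))
    out = GroupComparison(
        test="kruskal-wallis",
        statistic=float(stat),
        df=len(names) - 1,
        p=float(p),
        n_cases=n,
    )
    if post_hoc and p < alpha:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
        adj_alpha = alpha / len(pairs)
        for a, b in pairs:
            z, pp, r = rank_sum(groups[a], groups[b])
            out.post_hoc.append(
                {
                    "groups": (a, b),
                    "z": z,
                    "p": pp,
                    "effect_size_r": r,
                    "alpha_bonferroni": adj_alpha,
                    "significant": pp < adj_alpha,
                }
            )
    return out


def grouped_kruskal(
    values: np.ndarray, groups: np.ndarray, alpha: float = 0.05
) -> GroupComparison:
    """Robustness check: Kruskal-Wallis of an effect across recordings/animals."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    by = {str(g): values[groups == g] for g in np.unique(groups)}
    return layer_group_test(by, alpha=alpha, post_hoc=False)


# ---------------------------------------------------------------------------
# configuration and orchestration


@dataclass
class PipelineConfig:
    """Every analysis threshold in one place (all values documented defaults)."""

    speed_threshold_fraction: float = behavior.SPEED_THRESHOLD_FRACTION
    min_running_trials: int = behavior.MIN_RUNNING_TRIALS
    pupil_fraction: float = behavior.PUPIL_FRACTION
    csd_band_hz: tuple[float, float] = (1.0, 300.0)
    sink_window_s: tuple[float, float] = (0.0, 0.05)
    sink_k_sd: float = 3.0
    width_threshold_ms: float = 0.5
    sig_alpha: float = 0.01
    min_trials_per_condition: int = mod_mod.MIN_TRIALS_PER_CONDITION
    subsample_repeats: int = 100
    dcor_bin_start_s: float = 0.05
    dcor_bin_ceiling_s: float = 40.0
    dcor_shuffles: int = 50
    group_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for tup_field in ("csd_band_hz", "sink_window_s"):
            setattr(cfg, tup_field, tuple(getattr(cfg, tup_field)))
        return cfg


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):  # noqa: D102
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def run_pipeline(
    session: Session | str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full analysis on one session; return the report dict.

    Stage order: classify-trials -> csd -> classify-cells -> responses ->
    modulation -> dcor -> group stats. A stage failure aborts with the
    stage name; completed stage outputs written so far are retained. With
    identical config and seed the JSON report is byte-identical.
    """
    cfg = config or PipelineConfig()
    if not isinstance(session, Session):
        session = read_session(session)
    report: dict = {
        "session_id": session.session_id,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
        "stages": {},
    }
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    def _fail(stage: str, err: Exception) -> None:
        report["stages"][stage] = {"status": "failed", "error": str(err)}
        _write_report(report, out_path)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # -- classify-trials ----------------------------------------------------
    stage = "classify-trials"
    try:
        smoothed = behavior.smooth_running(session.running)
        labeling = behavior.label_trials(
            session.trials,
            smoothed,
            cfg.speed_threshold_fraction,
            cfg.min_running_trials,
        )
        session.trials = behavior.apply_labels(session.trials, labeling)
        report["stages"][stage] = {
            "status": "ok",
            "max_speed_cmps": labeling.max_speed,
            "n_running": labeling.n_running,
            "n_trials": len(session.trials),
            "included": bool(labeling.included),
        }
        log.info(
            "%s: %d/%d running trials, included=%s",
            stage, labeling.n_running, len(session.trials), labeling.included,
        )
    except Exception as e:  # noqa: BLE001
        _fail(stage, e)

    # -- csd ----------------------------------------------------------------
    stage = "csd"
    sink_global = None
    try:
        if session.lfp is not None:
            profile = csd_mod.compute_csd(session.lfp, cfg.csd_band_hz)
            profile = csd_mod.locate_sink(
                profile, session.trials, cfg.sink_window_s, k_sd=cfg.sink_k_sd
            )
            sink_global = profile.sink_channel_global
            report["stages"][stage] = {
                "status": "ok",
                "sink_channel": sink_global,
                "sink_latency_s": profile.sink_latency_s,
                "sink_detected": sink_global is not None,
            }
        else:
            report["stages"][stage] = {"status": "skipped", "reason": "no LFP"}
        session.units = csd_mod.assign_depths(
            session.units,
            sink_global,
            session.lfp.spacing_um if session.lfp is not None else 25.0,
        )
    except Exception as e:  # noqa: BLE001
        _fail(stage, e)

    # -- classify-cells -----------------------------------------------------
    stage = "classify-cells"
    try:
        n_ns = n_rs = 0
        for u in session.units:
            if u.waveforms is None:
                continue
            f = waveform_features(u.peak_waveform, u.waveform_rate_hz)
            u.cell_class = classify_unit(f, cfg.width_threshold_ms)
            n_ns += u.cell_class == "NS"
            n_rs += u.cell_class == "RS"
        report["stages"][stage] = {"status": "ok", "n_ns": n_ns, "n_rs": n_rs}
    except Exception as e:  # noqa: BLE001
        _fail(stage, e)

    # -- responses ----------------------------------------------------------
    stage = "responses"
    try:
        resp = response_table(session)
        if out_path is not None:
            resp.to_csv(out_path / "responses.tsv", sep="\t", index=False,
                        float_format="%.17g")
        n_sig = int(resp.groupby("unit_id")["sig_increase"].first().sum())
        report["stages"][stage] = {
            "status": "ok",
            "n_units": len(session.units),
            "n_sound_responsive": n_sig,
        }
    except Exception as e:  # noqa: BLE001
        _fail(stage, e)

    # -- modulation ---------------------------------------------------------
    stage = "modulation"
    modulation_df = None
    try:
        modulation_df = mod_mod.compute_modulation(
            session, cfg.min_trials_per_condition
        )
        if out_path is not None:
            modulation_df.to_csv(out_path / "modulation.tsv", sep="\t",
                                 index=False, float_format="%.17g")
        st: dict = {"status": "ok"}
        if report["stages"]["classify-trials"]["included"]:
            try:
                add = mod_mod.additivity_test(modulation_df)
                st["additivity"] = asdict(add)
            except ValueError as e:
                st["additivity"] = {"skipped": str(e)}
            try:
                sub = mod_mod.matched_subsample_mi(
                    session, modulation_df, cfg.subsample_repeats,
                    np.random.default_rng(cfg.seed),
                )
                st["matched_subsample"] = {
                    "running_mean_mi": sub.running_mean,
                    "sitting_mean_mi": sub.mean,
                    "sitting_sem": sub.sem,
                    "sitting_range": list(sub.range),
                    "mean_p": sub.mean_p,
                    "n_repeats": sub.n_repeats,
                }
            except ValueError as e:
                st["matched_subsample"] = {"skipped": str(e)}
        else:
            st["running_analyses"] = "skipped: fewer running trials than floor"
        report["stages"][stage] = st
    except Exception as e:  # noqa: BLE001
        _fail(stage, e)

    # -- dcor ---------------------------------------------------------------
    stage = "dcor"
    try:
        sweep = timescale.dcor_sweep(
            session.units,
            behavior.smooth_running(session.running),
            session.duration_s,
            timescale.bin_ladder(cfg.dcor_bin_start_s, cfg.dcor_bin_ceiling_s),
            cfg.dcor_shuffles,
            np.random.default_rng(cfg.seed + 1),
        )
        if out_path is not None:
            sweep.to_frame().to_csv(out_path / "dcor_sweep.tsv", sep="\t",
                                    index=False, float_format="%.17g")
        i100 = int(np.argmin(np.abs(sweep.bin_sizes_s - 0.1)))
        report["stages"][stage] = {
            "status": "ok",
            "dcor_100ms_raw": sweep.dcor_raw[i100],
            "dcor_100ms_corrected": sweep.dcor_corrected[i100],
            "dcor_100ms_p": sweep.p_value[i100],
            "peak_bin_s": sweep.peak_bin_s,
            "n_shuffles": sweep.n_shuffles,
        }
    except Exception as e:  # noqa: BLE001
        _fail(stage, e)

    # -- group-stats --------------------------------------------------------
    stage = "group-stats"
    try:
        st = {"status": "ok"}
        if modulation_df is not None:
            # L1 is reported but excluded from layer-group statistics (the
            # laminar groups of interest are L2/3-L6).
            by_layer = {
                layer: grp["running_effect"].to_numpy(float)
                for layer, grp in modulation_df.groupby("layer")
                if layer in ("L2/3", "L4", "L5", "L6")
            }
            by_layer = {
                k: v[np.isfinite(v)] for k, v in by_layer.items()
            }
            by_layer = {k: v for k, v in by_layer.items() if v.size > 0}
            if len(by_layer) >= 2:
                cmp_ = layer_group_test(by_layer, cfg.group_alpha)
                st["running_effect_by_layer"] = asdict(cmp_)
            else:
                st["running_effect_by_layer"] = {
                    "skipped": "insufficient laminar groups (sink undetected "
                    "or too few assigned units)"
                }
        report["stages"][stage] = st
    except Exception as e:  # noqa: BLE001
        _fail(stage, e)

    _write_report(report, out_path)
    return report


def _write_report(report: dict, out_path: Path | None) -> None:
    if out_path is not None:
        (out_path / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, cls=_ReportEncoder) + "\n"
        )
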