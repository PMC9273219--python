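"""Per-trial metric orchestration, group statistics, and reporting.

``run_worm_metrics`` composes the preprocessing, spectral, correlation,
state-dynamics, and quiescence modules into one tidy row per trial
(:class:`WormMetrics`); group comparisons follow the one-way-ANOVA +
Sidak-adjusted-pairwise convention, and all group summaries are means of
per-worm values (never pooled-neuron means).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import correlation, quiescence, spectral, states
from .errors import SampleSizeError
from .kinetics import extract_transitions, summarize_kinetics
from .preprocess import normalize_dff
from .trace import CalciumTraceSet
from .tvdiff import tv_differentiate, DEFAULT_ALPHA, DEFAULT_ITERATIONS

logger = logging.getLogger("wormdyn")


@dataclass
class MetricConfig:
    """Configuration shared by all per-trial metric computations."""

    n_sel: int = 40
    edge_q: float = 0.40
    psd_source: str = "dff"          # "dff" | "derivative"
    angle_window_s: float = 3.0
    angle_k: int = 3
    low_angle_cutoff: float = 30.0   # deg
    dff_percentile: float = 0.01
    tv_alpha: float = DEFAULT_ALPHA
    tv_iterations: int = DEFAULT_ITERATIONS
    top_frame_fraction: float = 0.25
    quiescence_ratio: float = 1.0 / 3.0
    global_threshold: float = 0.70


@dataclass
class WormMetrics:
    """One animal's derived scalar metrics; missing metrics are None."""

    trial_id: str
    condition: str
    spectral_edge_40: float | None = None
    neg_prop: float | None = None
    pos_prop: float | None = None
    time_in_quiescence: float | None = None
    angle_low_bin_mass: float | None = None
    explained_var_1to5: tuple[float, ...] | None = None
    duty_ratio: float | None = None
    mean_rise_time: float | None = None
    mean_fall_time: float | None = None
    transient_frequency: float | None = None


@dataclass
class GroupComparison:
    metric: str
    anova_F: float
    anova_p: float
    pairwise: list[tuple[str, str, float]] = field(default_factory=list)


def run_worm_metrics(traces: CalciumTraceSet,
                     config: MetricConfig | None = None,
                     kind: str = "population",
                     keep_intermediates: bool = False) -> WormMetrics:
    """Compute all applicable metrics for one trial.

    kind="population" fills the multi-neuron metrics and leaves the
    single-neuron kinetics fields missing; kind="ava" does the reverse.
    A failing stage logs its cause and leaves that metric missing; the
    remaining stages still run. With ``keep_intermediates`` the returned
    object carries an ``artifacts`` dict of intermediate results.
    """
    config = config or MetricConfig()
    m = WormMetrics(trial_id=traces.trial_id, condition=traces.condition)
    artifacts: dict = {}

    if kind == "ava":
        try:
            dff = normalize_dff(traces, mode="trace_mean")
            series = dff.dff[0]
            events = extract_transitions(series, traces.sampling_rate)
            summary = summarize_kinetics(events, traces.duration,
                                         traces.sampling_rate)
            m.duty_ratio = summary.duty_ratio
            m.mean_rise_time = summary.mean_rise_time
            m.mean_fall_time = summary.mean_fall_time
            m.transient_frequency = summary.transient_frequency
            artifacts["events"] = events
            artifacts["kinetics"] = summary
        except Exception:
            logger.exception("kinetics stage failed for %s", traces.trial_id)
        if keep_intermediates:
            m.artifacts = artifacts  # type: ignore[attr-defined]
        return m
    if kind != "population":
        raise ValueError(f"unknown trial kind {kind!r}")

    dff = normalize_dff(traces, mode="lowest_percentile",
                        percentile=config.dff_percentile)

    try:
        psd = spectral.compute_psd(dff)
        mean_psd, cumulative = spectral.mean_normalized_psd([psd])
        m.spectral_edge_40 = spectral.spectral_edge(
            mean_psd, q=config.edge_q).edge_hz
        artifacts["psd"] = psd
        artifacts["cumulative_power"] = cumulative
    except Exception:
        logger.exception("spectral stage failed for %s", traces.trial_id)

    try:
        sel = correlation.select_active_neurons(dff, n_sel=config.n_sel)
        ddt = tv_differentiate(dff, alpha=config.tv_alpha,
                               iterations=config.tv_iterations)
        pairs = correlation.pairwise_correlations(ddt, sel)
        props = correlation.correlation_proportions(pairs)
        m.neg_prop = props.neg_prop
        m.pos_prop = props.pos_prop
        artifacts["pairs"] = pairs
        artifacts["selected"] = sel
    except Exception:
        logger.exception("correlation stage failed for %s", traces.trial_id)

    try:
        traj = states.run_pca(dff, k=config.angle_k)
        ang = states.angular_changes(traj, traces.sampling_rate,
                                     window_s=config.angle_window_s)
        m.angle_low_bin_mass = states.low_angle_mass(
            ang, cutoff_deg=config.low_angle_cutoff)
        ev = traj.explained_var
        m.explained_var_1to5 = tuple(float(v) for v in ev[:5])
        artifacts["pca"] = traj
        artifacts["angles"] = ang
    except Exception:
        logger.exception("state-dynamics stage failed for %s", traces.trial_id)

    try:
        prof = quiescence.quiescence_profile(
            dff, top_frame_fraction=config.top_frame_fraction,
            quiescence_ratio=config.quiescence_ratio,
            global_threshold=config.global_threshold)
        m.time_in_quiescence = prof.time_in_quiescence
        artifacts["quiescence"] = prof
    except Exception:
        logger.exception("quiescence stage failed for %s", traces.trial_id)

    if keep_intermediates:
        m.artifacts = artifacts  # type: ignore[attr-defined]
    return m


_SCALAR_METRICS = ["spectral_edge_40", "neg_prop", "pos_prop",
                   "time_in_quiescence", "angle_low_bin_mass", "duty_ratio",
                   "mean_rise_time", "mean_fall_time", "transient_frequency"]


def metrics_table(rows: list[WormMetrics]) -> pd.DataFrame:
    """Tidy per-worm metrics table (one row per trial)."""
    recs = []
    for r in rows:
        d = asdict(r)
        ev = d.pop("explained_var_1to5")
        for i in range(5):
            d[f"explained_var_{i + 1}"] = (ev[i] if ev is not None
                                           and len(ev) > i else None)
        recs.append(d)
    cols = (["trial_id", "condition"] + _SCALAR_METRICS
            + [f"explained_var_{i + 1}" for i in range(5)])
    df = pd.DataFrame.from_records(recs)
    return df.reindex(columns=cols)


def compare_groups(table: pd.DataFrame, metric: str,
                   groups: list[str] | None = None,
                   contrasts: list[tuple[str, str]] | None = None
                   ) -> GroupComparison:
    """One-way ANOVA across groups plus Sidak-adjusted pairwise contrasts.

    ``p_adj = 1 - (1 - p)^m`` over the m requested contrasts (all pairs by
    default). Each group needs >= 2 rows with the metric present.
    """
    if groups is None:
        groups = list(dict.fromkeys(table["condition"]))
    if len(groups) < 2:
        raise SampleSizeError("need at least 2 groups")
    samples = {}
    for g in groups:
        vals = table.loc[table["condition"] == g, metric].dropna().to_numpy()
        if vals.size < 2:
            raise SampleSizeError(
                f"group {g!r} has {vals.size} values for {metric!r}; need >= 2")
        samples[g] = vals
    F, p = stats.f_oneway(*samples.values())
    if contrasts is None:
        contrasts = list(itertools.combinations(groups, 2))
    mcomp = len(contrasts)
    pairwise = []
    for a, b in contrasts:
        _, praw = stats.ttest_ind(samples[a], samples[b], equal_var=True)
        padj = float(1.0 - (1.0 - praw) ** mcomp)
        pairwise.append((a, b, min(max(padj, 0.0), 1.0)))
    return GroupComparison(metric=metric, anova_F=float(F), anova_p=float(p),
                           pairwise=pairwise)


def report(table: pd.DataFrame,
           comparisons: list[GroupComparison] | None = None,
           out_dir: str | None = None) -> str:
    """Human-readable summary: per-condition mean +/- SEM for each metric,
    plus any group comparisons. Optionally written to ``out_dir``."""
    lines = ["wormdyn metrics report", "=" * 40]
    if table is None or len(table) == 0:
        lines.append("no data")
    else:
        conditions = list(dict.fromkeys(table["condition"]))
        for metric in _SCALAR_METRICS:
            if metric not in table or table[metric].dropna().empty:
                continue
            lines.append(f"\n{metric}:")
            for c in conditions:
                vals = table.loc[table["condition"] == c, metric].dropna()
                if vals.empty:
                    lines.append(f"  {c}: no data")
                    continue
                mean = vals.mean()
                sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 \
                    else float("nan")
                lines.append(f"  {c}: {mean:.4f} +/- {sem:.4f} SEM "
                             f"(n={len(vals)})")
        if comparisons:
            lines.append("\ngroup comparisons (ANOVA + Sidak):")
            for comp in comparisons:
                lines.append(f"  {comp.metric}: F={comp.anova_F:.3f} "
                             f"p={comp.anova_p:.4g}")
                for a, b, padj in comp.pairwise:
                    lines.append(f"    {a} vs {b}: p_adj={padj:.4g}")
        elif len(conditions) < 2:
            lines.append("\n(single condition: no comparison section)")
    text = "\n".join(lines) + "\n"
    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.txt").write_text(text)
        if table is not None and len(table):
            table.to_csv(out / "metrics.csv", index=False)
            _render_metric_figures(table, out)
    return text


def _render_metric_figures(table: pd.DataFrame, out_dir) -> None:
    """Per-condition mean +/- SEM bar chart for each populated metric."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conditions = list(dict.fromkeys(table["condition"]))
    present = [m for m in _SCALAR_METRICS
               if m in table and not table[m].dropna().empty]
    if not present:
        return
    fig, axes = plt.subplots(1, len(present),
                             figsize=(2.2 * len(present), 3.0))
    axes = np.atleast_1d(axes)
    for ax, metric in zip(axes, present):
        means, sems = [], []
        for c in conditions:
            vals = table.loc[table["condition"] == c, metric].dropna()
            means.append(vals.mean())
            sems.append(vals.std(ddof=1) / np.sqrt(len(vals))
                        if len(vals) > 1 else 0.0)
        ax.bar(range(len(conditions)), means, yerr=sems, capsize=3,
               color="#4878a8")
        ax.set_xticks(range(len(conditions)))
        ax.set_xticklabels(conditions, rotation=45, ha="right", fontsize=7)
        ax.set_title(metric, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_dir / "metrics.png", dpi=120)
    plt.close(fig)
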