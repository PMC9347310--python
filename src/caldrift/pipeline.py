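"""End-to-end orchestration: simulate/load → preprocess → responsiveness
→ cross-day change → specificity → group statistics → report.

Every stage's randomness draws from a named sub-seed derived from the
run seed and the entity being tested (neuron, stimulus, day pair), so
results are bit-reproducible and independent of iteration order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from . import __version__
from .preprocess import SessionRecording, extract_trials
from .responsiveness import ResponsivenessResult, stimulus_responsiveness_test, sound_responsive
from .specificity import day_stimulus_anova
from .stability import (
    ChangeRecord,
    cross_day_change_test,
    interval_pairs,
    neuron_changed,
    percent_changed,
    profile_euclidean_distance,
)
from .group_stats import (
    CategoryProportions,
    ContingencyTable2x2,
    bootstrap_proportion_test,
    chi2_2x2,
    fisher_exact_2x2,
    rank_sum_test,
    two_proportion_z,
)
from .synth import CXS, PT, GroundTruth, StimulusSet, SynthConfig, make_experiment, make_stimulus_set

logger = logging.getLogger("caldrift")

__all__ = ["RunConfig", "ExperimentAnalysis", "analyze_experiment", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of one reproducible pipeline run."""

    seed: int = 0
    out_dir: str | None = None
    session_paths: list[str] = field(default_factory=list)
    stimulus_classes: list[str] = field(default_factory=list)
    synth: dict = field(default_factory=dict)  # SynthConfig overrides when simulating
    simulate: bool = True
    n_shuffles: int = 1000
    resp_quantile: float = 0.975
    change_quantile: float = 0.95
    margin: float = 0.10
    alpha: float = 0.05
    response_window_s: tuple[float, float] = (0.0, 1.5)
    prestim_window_s: tuple[float, float] = (-1.5, 0.0)
    run_anova: bool = True  # the specificity stage can be skipped for speed

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        for key in ("response_window_s", "prestim_window_s"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _subrng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(t) & 0x7FFFFFFF for t in tags])


@dataclass
class ExperimentAnalysis:
    """All tables produced by :func:`analyze_experiment`."""

    trials: pd.DataFrame
    responsiveness: pd.DataFrame
    sound_responsive: pd.DataFrame
    change_records: pd.DataFrame
    neuron_changes: pd.DataFrame
    distances: pd.DataFrame
    anova: pd.DataFrame
    summary: pd.DataFrame
    group_tests: dict


def _collect_trials(
    sessions: list[SessionRecording], cfg: RunConfig
) -> pd.DataFrame:
    frames = []
    for s in sessions:
        t = extract_trials(
            s,
            response_window_s=cfg.response_window_s,
            prestim_window_s=cfg.prestim_window_s,
        )
        n_exc = int(t["excluded"].sum())
        logger.info(
            "day %d: %d neurons, %d trials, %d excluded",
            s.day_index, s.n_neurons, len(t), n_exc,
        )
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def _responsiveness_tables(
    trials: pd.DataFrame,
    classes: np.ndarray,
    cfg: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(neuron, day, stimulus) responsiveness and per-(neuron, day,
    protocol) Bonferroni sound-responsiveness."""
    ok = trials[~trials["excluded"]]
    resp_groups = {
        k: v["response_mag"].to_numpy()
        for k, v in ok.groupby(["neuron_id", "day", "stimulus_id"])
    }
    protocols = sorted(set(classes))
    stim_of = {p: np.nonzero(classes == p)[0] for p in protocols}
    pre_groups: dict[tuple, np.ndarray] = {}
    for (n, d), g in ok.groupby(["neuron_id", "day"]):
        for p in protocols:
            sel = g[g["stimulus_id"].isin(stim_of[p])]
            pre_groups[(n, d, p)] = sel["prestim_mag"].to_numpy()

    rows = []
    sr_rows = []
    neurons = sorted(trials["neuron_id"].unique())
    days = sorted(trials["day"].unique())
    for n in neurons:
        for d in days:
            for p in protocols:
                results: list[ResponsivenessResult] = []
                pre = pre_groups.get((n, d, p), np.empty(0))
                for s in stim_of[p]:
                    sound = resp_groups.get((n, d, s), np.empty(0))
                    if sound.size < 3 or pre.size == 0:
                        rows.append((n, d, s, p, np.nan, np.nan, False, False))
                        continue
                    r = stimulus_responsiveness_test(
                        sound, pre,
                        n_shuffles=cfg.n_shuffles,
                        quantile=cfg.resp_quantile,
                        margin=cfg.margin,
                        seed=_subrng(cfg.seed, 1, n, d, s),
                        neuron_id=n, day=d, stimulus_id=s,
                    )
                    results.append(r)
                    rows.append(
                        (n, d, s, p, r.observed_diff, r.shuffle_quantile,
                         r.margin_pass, r.responsive)
                    )
                sr = sound_responsive(
                    results, n_stimuli=len(stim_of[p]), quantile=cfg.resp_quantile
                )
                sr_rows.append((n, d, p, sr))
    resp_df = pd.DataFrame(
        rows,
        columns=["neuron_id", "day", "stimulus_id", "protocol",
                 "observed_diff", "quantile", "margin_pass", "responsive"],
    )
    sr_df = pd.DataFrame(
        sr_rows, columns=["neuron_id", "day", "protocol", "sound_responsive"]
    )
    return resp_df, sr_df


def analyze_experiment(
    sessions: list[SessionRecording],
    stimulus_classes: list[str],
    cfg: RunConfig,
) -> ExperimentAnalysis:
    """Run the full drift analysis on a set of daily sessions.

    ``stimulus_classes`` tags each stimulus id with its protocol (PT or
    CxS); the two protocols are analyzed separately and compared by the
    group tests. Cross-day comparisons cover every day pair of every
    interval, pooling pairs of equal interval ("with repetitions").
    """
    classes = np.asarray(stimulus_classes)
    protocols = sorted(set(classes.tolist()))
    stim_of = {p: np.nonzero(classes == p)[0] for p in protocols}
    n_days = len(sessions)

    trials = _collect_trials(sessions, cfg)
    resp_df, sr_df = _responsiveness_tables(trials, classes, cfg)
    logger.info("responsiveness: %d tests, %.1f%% responsive",
                len(resp_df), 100 * resp_df["responsive"].mean())

    resp_lookup = {
        (r.neuron_id, r.day, r.stimulus_id): bool(r.responsive)
        for r in resp_df.itertuples()
    }
    sr_lookup = {
        (r.neuron_id, r.day, r.protocol): bool(r.sound_responsive)
        for r in sr_df.itertuples()
    }
    ok = trials[~trials["excluded"]]
    trial_arrays = {
        k: v["response_mag"].to_numpy()
        for k, v in ok.groupby(["neuron_id", "day", "stimulus_id"])
    }
    neurons = sorted(trials["neuron_id"].unique())

    change_rows, neuron_rows, dist_rows, anova_rows = [], [], [], []
    for p in protocols:
        stims = stim_of[p]
        for interval, pairs in interval_pairs(n_days).items():
            for (d1, d2) in pairs:
                for n in neurons:
                    n_sr = sr_lookup.get((n, d1, p), False) or sr_lookup.get((n, d2, p), False)
                    # pooled z-scoring across the pair and the protocol
                    pool = np.concatenate(
                        [trial_arrays.get((n, d, s), np.empty(0)) for d in (d1, d2) for s in stims]
                    )
                    if pool.size < 2 or pool.std() == 0:
                        logger.info("neuron %d pair (%d,%d) %s: skipped (degenerate pool)", n, d1, d2, p)
                        continue
                    mu, sigma = pool.mean(), pool.std()

                    records: list[ChangeRecord] = []
                    z_trials = {}
                    for s in stims:
                        z1 = (trial_arrays.get((n, d1, s), np.empty(0)) - mu) / sigma
                        z2 = (trial_arrays.get((n, d2, s), np.empty(0)) - mu) / sigma
                        z_trials[s] = (z1, z2)
                        if z1.size < 3 or z2.size < 3:
                            continue
                        included = resp_lookup.get((n, d1, s), False) or resp_lookup.get((n, d2, s), False)
                        rec = cross_day_change_test(
                            z1, z2,
                            n_shuffles=cfg.n_shuffles,
                            quantile=cfg.change_quantile,
                            margin=cfg.margin,
                            seed=_subrng(cfg.seed, 2, n, s, d1, d2),
                            neuron_id=n, stimulus_id=s, day_pair=(d1, d2),
                            included=included,
                        )
                        records.append(rec)
                        change_rows.append(
                            (p, interval, n, s, d1, d2, rec.observed_change,
                             rec.change_quantile, rec.magnitude_pass,
                             rec.significant, rec.included)
                        )
                    if n_sr and records:
                        neuron_rows.append(
                            (p, interval, n, d1, d2,
                             neuron_changed(records, n_stimuli=len(stims),
                                            quantile=cfg.change_quantile))
                        )
                        prof1 = np.array([z_trials[s][0].mean() if z_trials[s][0].size else np.nan for s in stims])
                        prof2 = np.array([z_trials[s][1].mean() if z_trials[s][1].size else np.nan for s in stims])
                        if not (np.isnan(prof1).any() or np.isnan(prof2).any()):
                            dist_rows.append(
                                (p, interval, n, d1, d2,
                                 profile_euclidean_distance(prof1, prof2))
                            )
                        if not cfg.run_anova:
                            continue
                        # stimulus-specificity ANOVA on the z-scored trials
                        adf = pd.DataFrame(
                            [
                                (v, d, s)
                                for s in stims
                                for d, z in zip((d1, d2), z_trials[s])
                                for v in z
                            ],
                            columns=["response_mag", "day", "stimulus_id"],
                        )
                        try:
                            res = day_stimulus_anova(
                                adf, alpha=cfg.alpha, neuron_id=n, day_pair=(d1, d2)
                            )
                            anova_rows.append(
                                (p, interval, n, d1, d2, res.F_interaction,
                                 res.p_interaction, res.omega_squared, res.significant)
                            )
                        except ValueError as e:
                            logger.info("neuron %d pair (%d,%d) %s: ANOVA skipped (%s)", n, d1, d2, p, e)

    change_df = pd.DataFrame(
        change_rows,
        columns=["protocol", "interval", "neuron_id", "stimulus_id", "day1", "day2",
                 "observed_change", "quantile", "magnitude_pass", "significant", "included"],
    )
    neuron_df = pd.DataFrame(
        neuron_rows, columns=["protocol", "interval", "neuron_id", "day1", "day2", "changed"]
    )
    dist_df = pd.DataFrame(
        dist_rows, columns=["protocol", "interval", "neuron_id", "day1", "day2", "distance"]
    )
    anova_df = pd.DataFrame(
        anova_rows,
        columns=["protocol", "interval", "neuron_id", "day1", "day2",
                 "F_interaction", "p_interaction", "omega_squared", "significant"],
    )

    summary = _summarize(change_df, neuron_df, dist_df, anova_df, protocols, n_days)
    group = _group_tests(change_df, neuron_df, dist_df, anova_df, cfg)
    return ExperimentAnalysis(
        trials=trials,
        responsiveness=resp_df,
        sound_responsive=sr_df,
        change_records=change_df,
        neuron_changes=neuron_df,
        distances=dist_df,
        anova=anova_df,
        summary=summary,
        group_tests=group,
    )


def _summarize(change_df, neuron_df, dist_df, anova_df, protocols, n_days) -> pd.DataFrame:
    rows = []
    for p in protocols:
        for interval in range(1, n_days):
            ch = change_df[(change_df.protocol == p) & (change_df.interval == interval)]
            inc = ch[ch.included]
            nd = neuron_df[(neuron_df.protocol == p) & (neuron_df.interval == interval)]
            dd = dist_df[(dist_df.protocol == p) & (dist_df.interval == interval)]
            ad = anova_df[(anova_df.protocol == p) & (anova_df.interval == interval)]
            rows.append(
                {
                    "protocol": p,
                    "interval": interval,
                    "included": len(inc),
                    "significant": int(inc.significant.sum()),
                    "percent_changed": (
                        percent_changed_from_counts(int(inc.significant.sum()), len(inc))
                        if len(inc) else np.nan
                    ),
                    "neurons": len(nd),
                    "neurons_changed": int(nd.changed.sum()) if len(nd) else 0,
                    "neurons_changed_fraction": float(nd.changed.mean()) if len(nd) else np.nan,
                    "mean_distance": float(dd.distance.mean()) if len(dd) else np.nan,
                    "anova_n": len(ad),
                    "anova_significant_fraction": float(ad.significant.mean()) if len(ad) else np.nan,
                    "mean_omega_squared": float(ad.omega_squared.mean()) if len(ad) else np.nan,
                }
            )
    return pd.DataFrame(rows)


def percent_changed_from_counts(n_significant: int, n_included: int) -> float:
    """100 × significant/included; the arithmetic behind percent-changed."""
    if n_included == 0:
        raise ValueError("no included records")
    return 100.0 * n_significant / n_included


def _group_tests(change_df, neuron_df, dist_df, anova_df, cfg: RunConfig) -> dict:
    """Protocol comparisons at interval 1 plus the multi-interval
    bootstrap, mirroring the published battery of group tests."""
    out: dict = {}
    if set(change_df.protocol.unique()) != {PT, CXS}:
        return out
    ch1 = change_df[(change_df.interval == 1) & change_df.included]
    cx = ch1[ch1.protocol == CXS]
    pt = ch1[ch1.protocol == PT]
    if len(cx) and len(pt):
        table = ContingencyTable2x2(
            int(cx.significant.sum()), int((~cx.significant).sum()),
            int(pt.significant.sum()), int((~pt.significant).sum()),
        )
        try:
            stat, p = chi2_2x2(table)
            out["percent_changed_chi2"] = {"statistic": stat, "p": p}
        except ValueError:
            pass
        odds, p_f, ci = fisher_exact_2x2(table)
        out["percent_changed_fisher"] = {"odds_ratio": odds, "p": p_f, "ci": ci}

    nd1 = neuron_df[neuron_df.interval == 1]
    cxn = nd1[nd1.protocol == CXS]
    ptn = nd1[nd1.protocol == PT]
    if len(cxn) and len(ptn) and (cxn.changed.sum() + ptn.changed.sum()) > 0:
        table = ContingencyTable2x2(
            int(cxn.changed.sum()), int((~cxn.changed).sum()),
            int(ptn.changed.sum()), int((~ptn.changed).sum()),
        )
        try:
            stat, p = chi2_2x2(table)
            out["neuron_changed_chi2"] = {"statistic": stat, "p": p}
        except ValueError:
            pass

    a1 = anova_df[anova_df.interval == 1]
    cxa = a1[a1.protocol == CXS]
    pta = a1[a1.protocol == PT]
    if len(cxa) and len(pta):
        try:
            z, p1, p2 = two_proportion_z(
                int(cxa.significant.sum()), len(cxa),
                int(pta.significant.sum()), len(pta),
            )
            out["anova_proportion_z"] = {"z": z, "p_one_sided": p1, "p_two_sided": p2}
        except ValueError:
            pass
        w, p = rank_sum_test(
            cxa.omega_squared.to_numpy(), pta.omega_squared.to_numpy()
        )
        out["omega_squared_rank_sum"] = {"rank_sum_cxs": w, "p": p}

    d1 = dist_df[dist_df.interval == 1]
    if len(d1[d1.protocol == CXS]) > 1 and len(d1[d1.protocol == PT]) > 1:
        t, p = sp_stats.ttest_ind(
            d1[d1.protocol == CXS].distance, d1[d1.protocol == PT].distance
        )
        out["distance_t_test"] = {"t": float(t), "p": float(p)}

    # multi-interval bootstrap on percent-changed (intervals as categories)
    intervals = sorted(change_df.interval.unique())
    cats = {"labels": [], "n_ref": [], "k_ref": [], "n_test": [], "k_test": []}
    for k in intervals:
        chk = change_df[(change_df.interval == k) & change_df.included]
        cxk, ptk = chk[chk.protocol == CXS], chk[chk.protocol == PT]
        if len(cxk) == 0 or len(ptk) == 0:
            continue
        cats["labels"].append(f"{k}-day")
        cats["n_ref"].append(len(cxk))
        cats["k_ref"].append(int(cxk.significant.sum()))
        cats["n_test"].append(len(ptk))
        cats["k_test"].append(int(ptk.significant.sum()))
    if cats["labels"]:
        props = CategoryProportions(**{k: tuple(v) for k, v in cats.items()})
        out["multi_interval_bootstrap"] = {
            "p": bootstrap_proportion_test(
                props, seed=_subrng(cfg.seed, 3)
            ),
            "categories": cats["labels"],
        }
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the whole pipeline per ``config`` and return the report.

    With ``config.simulate`` a synthetic experiment is generated from
    ``config.synth`` overrides; otherwise sessions are read from
    ``config.session_paths`` (HDF5) with ``config.stimulus_classes``
    naming each stimulus's protocol. Writes intermediate CSV tables and
    a JSON + Markdown report when ``config.out_dir`` is set. Idempotent
    for a fixed seed.
    """
    if config.simulate:
        synth_cfg = SynthConfig(**{**config.synth, "seed": config.seed})
        stimuli = make_stimulus_set(seed=config.seed)
        sessions, truth = make_experiment(synth_cfg, stimuli)
        classes = stimuli.sound_class
    else:
        from .session_io import read_session

        if not config.session_paths:
            raise ValueError("no session paths and simulate=False")
        sessions = [read_session(p) for p in config.session_paths]
        classes = config.stimulus_classes
        if not classes:
            raise ValueError("stimulus_classes required when loading sessions")
        truth = None

    analysis = analyze_experiment(sessions, classes, config)

    report = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "caldrift_version": __version__,
            "numpy_version": np.__version__,
        },
        "summary": analysis.summary.to_dict(orient="records"),
        "group_tests": analysis.group_tests,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        analysis.trials.to_csv(out / "trials.csv", index=False)
        analysis.responsiveness.to_csv(out / "responsiveness.csv", index=False)
        analysis.sound_responsive.to_csv(out / "sound_responsive.csv", index=False)
        analysis.change_records.to_csv(out / "change_records.csv", index=False)
        analysis.neuron_changes.to_csv(out / "neuron_changes.csv", index=False)
        analysis.distances.to_csv(out / "distances.csv", index=False)
        analysis.anova.to_csv(out / "anova.csv", index=False)
        analysis.summary.to_csv(out / "summary.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        (out / "report.md").write_text(_report_markdown(report, analysis))
        if truth is not None:
            (out / "ground_truth.json").write_text(truth.to_json())
    return report


def _report_markdown(report: dict, analysis: ExperimentAnalysis) -> str:
    lines = ["# caldrift run report", ""]
    prov = report["provenance"]
    lines += [f"- config hash: `{prov['config_hash']}`",
              f"- seed: {prov['seed']}",
              f"- caldrift {prov['caldrift_version']}, numpy {prov['numpy_version']}", ""]
    summary = analysis.summary
    header = "| " + " | ".join(summary.columns) + " |"
    sep = "|" + "|".join("---" for _ in summary.columns) + "|"
    body = [
        "| " + " | ".join(
            f"{v:.4g}" if isinstance(v, float) else str(v) for v in row
        ) + " |"
        for row in summary.itertuples(index=False)
    ]
    lines += ["## Per-protocol, per-interval summary", "", header, sep, *body, ""]
    lines += ["## Group tests", ""]
    for name, val in report["group_tests"].items():
        lines.append(f"- **{name}**: {json.dumps(val, default=float)}")
    lines.append("")
    return "\n".join(lines)
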