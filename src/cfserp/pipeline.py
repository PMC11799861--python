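"""End-to-end study replication on a synthetic cohort.

``run_study`` composes every stage — per-subject contrast calibration,
main-experiment simulation with between-block recalibration, epoch
simulation and preprocessing, factorial cluster-based permutation tests in
the early (150–300 ms, posterior) and late (300–600 ms, centro-parietal)
windows separately for CFS and noCFS, and the follow-up t tests / Bayes
factors on cluster averages.  ``simulate_null_study`` estimates the
family-wise error of the cluster test on effect-free data.

All randomness is explicit: every stage draws from streams spawned from the
single study seed, so identical configs give byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import (
    ClusterResult,
    cbp_test,
    cluster_table,
    extract_cluster_average,
)
from .preproc import ConditionMeans, RejectionCriteria, preprocess
from .sdt import (
    CalibrationError,
    detection_counts,
    discrimination_counts,
    dprime,
    exclusion_check,
    fit_contrast_levels,
    recalibrate_block,
)
from .stats import correlation_bf, holm, jzs_bf, rm_anova, ttest
from .synth import (
    EXPRESSIONS,
    MAIN_LEVELS,
    EffectSpec,
    ObserverParams,
    SensorGraph,
    TrialSchedule,
    make_calibration_schedule,
    make_layout,
    make_main_schedule,
    roi_mask,
    simulate_epochs,
    simulate_observer,
)

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_study",
    "simulate_null_study",
    "simulate_main_with_recalibration",
]


@dataclass
class StudyConfig:
    """Everything needed for a full synthetic study run.

    Desk-scale defaults (12 subjects, 64 channels, 500 permutations) keep a
    complete run interactive; ``full_scale()`` switches to the full design
    (48 subjects, 5000 permutations).
    """

    n_subjects: int = 12
    n_channels: int = 64
    neighbor_distance: float | None = None
    calib_contrasts: tuple[float, ...] = (0.05, 0.15, 0.25, 0.35)
    calib_n_per_condition: int = 48
    n_per_condition: int = 60
    n_blocks: int = 7
    prompt_fraction: float = 1 / 3
    recal_criterion: float = 0.3
    recal_reduction: float = 0.2
    exclusion_dprime: float = 1.0
    observer: ObserverParams = field(default_factory=ObserverParams)
    observer_slope_sd: float = 1.5
    observer_intercept_sd: float = 0.1
    effects: EffectSpec = field(default_factory=EffectSpec)
    rejection: RejectionCriteria = field(default_factory=RejectionCriteria)
    early_window: tuple[float, float] = (150.0, 300.0)
    late_window: tuple[float, float] = (300.0, 600.0)
    early_roi: str = "posterior"
    late_roi: str = "central"
    n_perm: int = 500
    alpha: float = 0.05
    cluster_alpha: float = 0.05
    n_windows: int = 2
    seed: int = 0

    def full_scale(self) -> "StudyConfig":
        return dataclasses.replace(self, n_subjects=48, n_perm=5000)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("expression_amplitude_early", "expression_amplitude_late"):
            d["effects"][key] = {
                f"{lev}|{'cfs' if c else 'nocfs'}": v
                for (lev, c), v in d["effects"][key].items()
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "observer" in d and isinstance(d["observer"], dict):
            d["observer"] = ObserverParams(**d["observer"])
        if "effects" in d and isinstance(d["effects"], dict):
            eff = dict(d["effects"])
            for key in ("expression_amplitude_early", "expression_amplitude_late"):
                if key in eff:
                    eff[key] = {
                        (k.split("|")[0], k.split("|")[1] == "cfs"): v
                        for k, v in eff[key].items()
                    }
            for tkey in ("early_seed", "late_seed"):
                if tkey in eff:
                    eff[tkey] = tuple(eff[tkey])
            d["effects"] = EffectSpec(**eff)
        if "rejection" in d and isinstance(d["rejection"], dict):
            d["rejection"] = RejectionCriteria(**d["rejection"])
        for tkey in ("calib_contrasts", "early_window", "late_window"):
            if tkey in d:
                d[tkey] = tuple(d[tkey])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """All stage outputs of one study run, with provenance."""

    config_digest: str
    seed: int
    n_simulated: int
    n_excluded: int
    excluded: list[dict]
    calibration: pd.DataFrame
    behavioral: pd.DataFrame
    behavioral_anova: pd.DataFrame
    clusters: pd.DataFrame
    followup: pd.DataFrame
    rejection: pd.DataFrame
    recalibration: pd.DataFrame

    @property
    def n_included(self) -> int:
        return self.n_simulated - self.n_excluded

    def save(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in (
            "calibration",
            "behavioral",
            "behavioral_anova",
            "clusters",
            "followup",
            "rejection",
            "recalibration",
        ):
            getattr(self, name).to_csv(out / f"{name}.tsv", sep="\t", index=False)
        meta = {
            "config_digest": self.config_digest,
            "seed": self.seed,
            "n_simulated": self.n_simulated,
            "n_excluded": self.n_excluded,
            "n_included": self.n_included,
            "excluded": self.excluded,
            "version": __version__,
        }
        (out / "report.json").write_text(json.dumps(meta, indent=1))
        return out


def _subject_observer(
    base: ObserverParams, rng: np.random.Generator, cfg: StudyConfig
) -> ObserverParams:
    """Individual observer: jittered detection line, same structure."""
    return dataclasses.replace(
        base,
        detect_slope_cfs=float(
            rng.normal(base.detect_slope_cfs, cfg.observer_slope_sd)
        ),
        detect_intercept_cfs=float(
            rng.normal(base.detect_intercept_cfs, cfg.observer_intercept_sd)
        ),
    )


def _calibrate_subject(
    params: ObserverParams, cfg: StudyConfig, rng: np.random.Generator
):
    """Run the constant-stimuli calibration, retrying on failure.

    Mirrors the experimenter re-running with an adjusted contrast grid when
    the fitted line is unusable; gives up after three attempts.
    """
    grid = np.array(cfg.calib_contrasts, dtype=float)
    last_err: Exception | None = None
    for _attempt in range(3):
        sched = make_calibration_schedule(
            cfg.calib_n_per_condition, grid, seed=int(rng.integers(2**31))
        )
        resp = simulate_observer(sched, params, seed=int(rng.integers(2**31)))
        levels = [lev for lev in sched.contrasts]
        ds = []
        for lev in levels:
            counts = detection_counts(
                resp, face_mask=resp.contrast_level.to_numpy() == lev
            )
            ds.append(dprime(counts)[0])
        try:
            return fit_contrast_levels([sched.contrasts[k] for k in levels], ds)
        except CalibrationError as err:
            last_err = err
            # adjust the grid toward the informative range: visible
            # throughout (negative medium) -> lower contrasts; flat or
            # inverted line -> raise contrasts
            factor = 0.5 if err.reason == "medium" else 1.5
            grid = np.clip(grid * factor, 0.0, 1.0)
            grid = np.unique(np.round(grid, 6))
            if len(grid) < 2:
                break
    raise CalibrationError(
        f"calibration failed after retries: {last_err}",
        reason=getattr(last_err, "reason", "slope"),
    )


def simulate_main_with_recalibration(
    contrasts: dict[str, float],
    params: ObserverParams,
    cfg: StudyConfig,
    seed: int,
) -> tuple[TrialSchedule, pd.DataFrame, pd.DataFrame]:
    """Simulate the main experiment block by block with contrast recalibration.

    After every block the pooled low+medium CFS d' is computed; if it
    exceeds the criterion both contrasts shrink by the reduction factor and
    subsequent blocks use (and record) the new values.  Returns the
    schedule, the full response table, and the per-block recalibration log.
    """
    rng = np.random.default_rng(seed)
    schedule = make_main_schedule(
        n_per_condition=cfg.n_per_condition,
        contrasts=contrasts,
        n_blocks=cfg.n_blocks,
        prompt_fraction=cfg.prompt_fraction,
        seed=int(rng.integers(2**31)),
    )
    current = dict(contrasts)
    parts, log = [], []
    for block_id, block in schedule.table.groupby("block"):
        block = block.copy()
        block["contrast_value"] = [
            current.get(lev, 0.0) for lev in block.contrast_level
        ]
        bsched = TrialSchedule(table=block, contrasts=dict(current))
        resp = simulate_observer(bsched, params, seed=int(rng.integers(2**31)))
        parts.append(resp)
        try:
            new, pooled_d = recalibrate_block(
                resp, current, cfg.recal_criterion, cfg.recal_reduction
            )
        except ValueError:
            # tiny blocks may lack catch or low/medium trials: skip the rule
            new, pooled_d = dict(current), float("nan")
        log.append(
            {
                "block": int(block_id),
                "pooled_dprime": pooled_d,
                "reduced": new["low"] != current["low"],
                "low": new["low"],
                "medium": new["medium"],
                "high": new["high"],
            }
        )
        current = new
    responses = pd.concat(parts, ignore_index=True)
    return schedule, responses, pd.DataFrame(log)


def _behavioral_summary(responses: pd.DataFrame, subject: int) -> pd.DataFrame:
    """Detection and discrimination d' per condition for one subject.

    Catch trials of the same visibility condition supply the false alarms
    for every face condition under that visibility.
    """
    rows = []
    lev = responses.contrast_level.to_numpy()
    expr = responses.expression.to_numpy()
    cfs = responses.cfs.to_numpy().astype(bool)
    for v in (True, False):
        catch_mask = (lev == "catch") & (cfs == v)
        for level in MAIN_LEVELS:
            for e in EXPRESSIONS:
                counts = detection_counts(
                    responses,
                    face_mask=(expr == e) & (lev == level) & (cfs == v),
                    catch_mask=catch_mask,
                )
                d, c = dprime(counts)
                rows.append(
                    {
                        "subject": subject,
                        "task": "detection",
                        "expression": e,
                        "contrast_level": level,
                        "cfs": v,
                        "dprime": d,
                        "criterion": c,
                    }
                )
            disc = discrimination_counts(
                responses, mask=(lev == level) & (cfs == v)
            )
            if disc.n_signal and disc.n_noise:
                d, c = dprime(disc)
                rows.append(
                    {
                        "subject": subject,
                        "task": "discrimination",
                        "expression": "both",
                        "contrast_level": level,
                        "cfs": v,
                        "dprime": d,
                        "criterion": c,
                    }
                )
    return pd.DataFrame(rows)


def _detection_cell_matrix(behavior: pd.DataFrame, cfs: bool) -> np.ndarray:
    """subject x (expression x contrast) detection d' matrix, cell order
    matching rm_anova's (A=expression, B=contrast, B fastest)."""
    det = behavior[(behavior.task == "detection") & (behavior.cfs == cfs)]
    piv = det.pivot_table(
        index="subject",
        columns=["expression", "contrast_level"],
        values="dprime",
    )
    cols = [(e, l) for e in EXPRESSIONS for l in MAIN_LEVELS]
    return piv[cols].to_numpy()


def _analysis_views(cm: ConditionMeans, graph: SensorGraph, cfg: StudyConfig):
    """(window name, visibility, restricted means, matching sub-adjacency)."""
    out = []
    for wname, window, roi in (
        ("early", cfg.early_window, cfg.early_roi),
        ("late", cfg.late_window, cfg.late_roi),
    ):
        mask = roi_mask(graph, roi)
        sub = cm.select(window=window, channels=mask)
        adj = graph.adjacency[np.ix_(mask, mask)]
        out.append((wname, sub, adj))
    return out


def run_study(config: StudyConfig, out_dir=None) -> StudyReport:
    """Execute calibration -> main experiment -> preprocessing -> CBP ->
    follow-up on a synthetic cohort; see the module docstring."""
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    layout = make_layout(cfg.n_channels, cfg.neighbor_distance)

    calib_rows, behav_rows, rej_rows, recal_rows = [], [], [], []
    excluded: list[dict] = []
    cm_parts: list[ConditionMeans] = []

    subject_seeds = root.spawn(cfg.n_subjects)
    for s, sseq in enumerate(subject_seeds):
        rng = np.random.default_rng(sseq)
        params = _subject_observer(cfg.observer, rng, cfg)
        try:
            calib = _calibrate_subject(params, cfg, rng)
        except CalibrationError as err:
            excluded.append({"subject": s, "reason": str(err)})
            continue
        calib_rows.append({"subject": s, **{k: v for k, v in calib.to_dict().items()
                                            if not isinstance(v, list)}})

        schedule, responses, recal = simulate_main_with_recalibration(
            calib.levels, params, cfg, seed=int(rng.integers(2**31))
        )
        recal.insert(0, "subject", s)
        recal_rows.append(recal)

        behav = _behavioral_summary(responses, s)
        behav_rows.append(behav)

        med = behav[
            (behav.task == "detection")
            & (behav.cfs)
            & (behav.contrast_level == "medium")
        ].dprime.mean()
        ok, reason = exclusion_check(med, cfg.exclusion_dprime)
        if not ok:
            excluded.append({"subject": s, "reason": reason})
            continue

        epochs = simulate_epochs(
            schedule,
            cfg.effects,
            layout,
            n_subjects=1,
            seed=int(rng.integers(2**31)),
        )
        cm, rej = preprocess(epochs, cfg.rejection)
        rej_rows.append({"subject": s, **dataclasses.asdict(rej)})
        cm_parts.append(cm)

    if not cm_parts:
        raise RuntimeError("all subjects excluded: nothing to analyze")
    included_behav = pd.concat(behav_rows, ignore_index=True)
    included_behav = included_behav[
        ~included_behav.subject.isin([e["subject"] for e in excluded])
    ]
    cm_all = ConditionMeans(
        data=np.concatenate([c.data for c in cm_parts], axis=0),
        cells=cm_parts[0].cells,
        times=cm_parts[0].times,
        sampling_rate=cm_parts[0].sampling_rate,
        channel_names=cm_parts[0].channel_names,
        n_trials_per_cell=np.concatenate(
            [c.n_trials_per_cell for c in cm_parts], axis=0
        ),
    )

    # behavioral ANOVA (2 expression x 3 contrast) per visibility condition
    anova_rows = []
    for v in (True, False):
        mat = _detection_cell_matrix(included_behav, v)
        for res in rm_anova(mat, (2, 3), ("expression", "contrast")):
            anova_rows.append(
                {
                    "cfs": v,
                    "effect": res.effect,
                    "F": res.statistic,
                    "df1": res.df[0],
                    "df2": res.df[1],
                    "p": res.p,
                    "epsilon_hat": res.epsilon_hat,
                }
            )
    # chance-level checks: one-sample BFs for low/medium CFS detection d'
    followup_rows = []
    n_inc = cm_all.n_subjects
    for level in ("low", "medium"):
        for e in EXPRESSIONS:
            vals = included_behav[
                (included_behav.task == "detection")
                & included_behav.cfs
                & (included_behav.contrast_level == level)
                & (included_behav.expression == e)
            ].dprime.to_numpy()
            res = ttest(vals, kind="one_sample", effect=f"d'({e},{level},CFS)=0")
            bf = jzs_bf(res.statistic, len(vals), kind="one_sample")
            followup_rows.append(
                {
                    "family": "behavior_chance",
                    "effect": res.effect,
                    "t": res.statistic,
                    "df": res.df[0],
                    "p": res.p,
                    "p_holm": np.nan,
                    "bf10": bf,
                    "bf01": 1 / bf,
                }
            )

    # cluster-based permutation tests
    cbp_seed_root = np.random.SeedSequence([cfg.seed, 0xC1A5])
    cbp_seeds = iter(cbp_seed_root.generate_state(64).tolist())
    all_clusters: list[tuple[str, bool, ClusterResult]] = []
    cluster_frames = []
    views = _analysis_views(cm_all, layout, cfg)
    for v in (True, False):
        for wname, sub, adj in views:
            for effect in ("expression", "contrast", "interaction"):
                clusters = cbp_test(
                    sub,
                    effect,
                    cfs=v,
                    adjacency=adj,
                    n_perm=cfg.n_perm,
                    alpha=cfg.alpha,
                    cluster_alpha=cfg.cluster_alpha,
                    n_windows=cfg.n_windows,
                    seed=int(next(cbp_seeds) % 2**31),
                )
                for cl in clusters:
                    all_clusters.append((wname, v, cl))
                tab = cluster_table(clusters)
                tab.insert(0, "window", wname)
                tab.insert(0, "cfs", v)
                cluster_frames.append(tab)
    clusters_df = pd.concat(cluster_frames, ignore_index=True)

    # follow-up on the best CFS early interaction cluster (if significant)
    early_sub = views[0][1]

    def _sig(wname, v, effect):
        cands = [
            cl
            for w, c, cl in all_clusters
            if w == wname and c == v and cl.effect == effect
            and cl.p_corrected is not None and cl.p_corrected <= cfg.alpha
        ]
        return cands[0] if cands else None

    inter = _sig("early", True, "interaction")
    if inter is not None:
        avg = extract_cluster_average(early_sub, inter)  # subj x cell
        diffs = {}
        for level in MAIN_LEVELS:
            i_f = early_sub.cells.index(("fearful", level, True))
            i_n = early_sub.cells.index(("neutral", level, True))
            diffs[level] = avg[:, i_f] - avg[:, i_n]
        # each contrast's expression difference vs zero
        zero_tests = [
            (lev, ttest(diffs[lev], kind="one_sample", effect=f"diff({lev}) vs 0"))
            for lev in MAIN_LEVELS
        ]
        adj_zero = holm([r.p for _, r in zero_tests])
        for (lev, res), ph in zip(zero_tests, adj_zero):
            bf = jzs_bf(res.statistic, n_inc, kind="one_sample")
            followup_rows.append(
                {
                    "family": "interaction_cluster",
                    "effect": res.effect,
                    "t": res.statistic,
                    "df": res.df[0],
                    "p": res.p,
                    "p_holm": ph,
                    "bf10": bf,
                    "bf01": 1 / bf,
                }
            )
        # pairwise contrast comparisons of the differences (printed-df
        # convention: pooled-variance independent test, df 2n-2)
        pairs = [("low", "high"), ("low", "medium"), ("medium", "high")]
        pair_tests = [
            (
                f"diff({a}) vs diff({b})",
                ttest(diffs[a], diffs[b], kind="independent"),
            )
            for a, b in pairs
        ]
        adj_pair = holm([r.p for _, r in pair_tests])
        for (name, res), ph in zip(pair_tests, adj_pair):
            bf = jzs_bf(res.statistic, n_inc, n_inc, kind="independent")
            followup_rows.append(
                {
                    "family": "interaction_cluster",
                    "effect": name,
                    "t": res.statistic,
                    "df": res.df[0],
                    "p": res.p,
                    "p_holm": ph,
                    "bf10": bf,
                    "bf01": 1 / bf,
                }
            )
        # residual-awareness control: cluster average vs detection d'
        det = included_behav[
            included_behav.cfs & (included_behav.task == "detection")
        ]
        for level in MAIN_LEVELS:
            dvals = (
                det[det.contrast_level == level]
                .groupby("subject")
                .dprime.mean()
                .to_numpy()
            )
            if len(dvals) == len(diffs[level]) and np.std(dvals) > 0:
                r, p, bf10 = correlation_bf(diffs[level], dvals)
                followup_rows.append(
                    {
                        "family": "awareness_correlation",
                        "effect": f"diff({level}) ~ d'({level})",
                        "t": r,
                        "df": len(dvals) - 2,
                        "p": p,
                        "p_holm": np.nan,
                        "bf10": bf10,
                        "bf01": 1 / bf10,
                    }
                )

    report = StudyReport(
        config_digest=cfg.digest(),
        seed=cfg.seed,
        n_simulated=cfg.n_subjects,
        n_excluded=len(excluded),
        excluded=excluded,
        calibration=pd.DataFrame(calib_rows),
        behavioral=included_behav.reset_index(drop=True),
        behavioral_anova=pd.DataFrame(anova_rows),
        clusters=clusters_df,
        followup=pd.DataFrame(followup_rows),
        rejection=pd.DataFrame(rej_rows),
        recalibration=pd.concat(recal_rows, ignore_index=True)
        if recal_rows
        else pd.DataFrame(),
    )
    if out_dir is not None:
        report.save(out_dir)
    return report


def simulate_null_study(
    config: StudyConfig | None = None,
    n_replicates: int = 200,
    effect: str = "expression",
    n_channels: int = 16,
    n_trials_per_cell: int = 4,
    n_perm: int = 500,
    window: tuple[float, float] = (144.0, 296.0),
    seed: int = 0,
) -> dict:
    """Empirical family-wise error of the cluster test under the null.

    Generates effect-free cohorts (all expression amplitudes zero) through
    the same generator -> preprocessing -> CBP path as a real run, at a
    reduced problem size, and reports the fraction of replicates with any
    cluster at p_raw <= alpha (single-window analysis) with a 95% binomial
    interval.
    """
    cfg = config or StudyConfig()
    null_effects = cfg.effects.zeroed()
    layout = make_layout(n_channels, cfg.neighbor_distance)
    root = np.random.SeedSequence([seed, 0x0F57])
    hits = 0
    for rep_seq in root.spawn(n_replicates):
        rng = np.random.default_rng(rep_seq)
        schedule = make_main_schedule(
            n_per_condition=n_trials_per_cell,
            contrasts={"low": 0.01, "medium": 0.02, "high": 0.32},
            n_blocks=1,
            prompt_fraction=0.0,
            seed=int(rng.integers(2**31)),
        )
        epochs = simulate_epochs(
            schedule,
            null_effects,
            layout,
            n_subjects=cfg.n_subjects,
            seed=int(rng.integers(2**31)),
        )
        cm, _ = preprocess(epochs, cfg.rejection)
        sub = cm.select(window=window)
        clusters = cbp_test(
            sub,
            effect,
            cfs=True,
            adjacency=layout.adjacency,
            n_perm=n_perm,
            alpha=cfg.alpha,
            cluster_alpha=cfg.cluster_alpha,
            n_windows=1,
            seed=int(rng.integers(2**31)),
        )
        if any(cl.p_raw is not None and cl.p_raw <= cfg.alpha for cl in clusters):
            hits += 1
    fwer = hits / n_replicates
    half = 1.96 * np.sqrt(cfg.alpha * (1 - cfg.alpha) / n_replicates)
    return {
        "n_replicates": n_replicates,
        "alpha": cfg.alpha,
        "fwer": fwer,
        "n_false_positive": hits,
        "nominal_interval": (cfg.alpha - half, cfg.alpha + half),
        "effect": effect,
    }
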