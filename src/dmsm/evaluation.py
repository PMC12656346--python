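"""Batch pairwise comparison and the statistical protocol.

Given a set of clips (from a manifest or generated in memory), every
unordered pair is scored with the selected method and classed as
same-player or cross-player. The separation statistic is the difference of
class means on the dissimilarity scale (cross − same; positive = the method
discriminates players), tested with Welch's two-sample t (the two classes
are not a paired design), checked for normality per class (Shapiro–Wilk),
and summarized with Cohen's d and a seeded percentile-bootstrap 95% CI.
Method-vs-method contrasts *are* paired — identical clip pairs scored by
both methods — and use the paired t-test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DmsmError, ParameterError, ValidationError
from .io_pose import ClipManifest, PoseSequence, read_pose_sequence
from .phases import PHASE_NAMES, detect_phases
from .preprocess import center_address, preprocess_sequence
from .similarity import (
    SimilarityConfig,
    compare,
    report_from_cached,
    resampled_phase_trajectories,
)
from .synth import SwingStyle, random_style, sample_player

logger = logging.getLogger(__name__)


@dataclass
class EvalTable:
    """All-pairs evaluation results plus per-clip failures."""

    df: pd.DataFrame
    method: str
    failures: list[tuple[str, str]] = field(default_factory=list)

    def values_by_class(self, column: str = "DS") -> tuple[np.ndarray, np.ndarray]:
        same = self.df.loc[self.df.pair_class == "same_player", column].to_numpy()
        cross = self.df.loc[self.df.pair_class == "cross_player", column].to_numpy()
        return same, cross

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class SeparationStats:
    mean_same: float
    mean_cross: float
    separation: float
    t_statistic: float
    p_value: float
    shapiro_p: tuple[float | None, float | None]
    cohens_d: float
    bootstrap_ci_95: tuple[float, float]
    n_same: int
    n_cross: int

    def __post_init__(self) -> None:
        lo, hi = self.bootstrap_ci_95
        if lo > hi:
            raise ValidationError("bootstrap CI bounds out of order")
        if self.separation * self.cohens_d < 0:
            raise ValidationError("Cohen's d sign must match the separation sign")


def _load_clips(source) -> list[PoseSequence]:
    if isinstance(source, ClipManifest):
        clips = []
        for rec in source:
            fmt = "landmark_records" if rec.path.endswith((".ndjson", ".landmarks")) else "csv"
            seq = read_pose_sequence(rec.path, fmt)
            seq.clip_id, seq.player_id = rec.clip_id, rec.player_id
            seq.handedness, seq.fps = rec.handedness, rec.fps
            clips.append(seq)
        return clips
    return list(source)


def pairwise_evaluation(
    source: ClipManifest | list[PoseSequence],
    method: str = "dmsm",
    cfg: SimilarityConfig | None = None,
) -> EvalTable:
    """Score every unordered clip pair; self-pairs are excluded by design.

    Clips that fail preprocessing or segmentation are dropped with a logged
    reason (recorded in ``failures``) rather than failing the batch.
    """
    cfg = cfg or SimilarityConfig()
    clips = _load_clips(source)
    if len(clips) < 2:
        raise ParameterError("need at least 2 clips")
    ids = [c.clip_id for c in clips]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate clip_id in evaluation input")

    rows: list[dict] = []
    failures: list[tuple[str, str]] = []

    if method == "dmsm":
        # segment and resample each clip once; pair scoring reuses the cache
        prepared = []
        for seq in clips:
            try:
                p = center_address(preprocess_sequence(seq, cfg.preprocess))
                seg = detect_phases(p, cfg.preprocess)
                cache = resampled_phase_trajectories(p, seg, cfg)
                prepared.append((seq, cache))
            except DmsmError as exc:
                logger.warning("clip %s excluded: %s", seq.clip_id, exc)
                failures.append((seq.clip_id, str(exc)))
        for (sa, ca), (sb, cb) in itertools.combinations(prepared, 2):
            rep = report_from_cached(ca, cb, cfg, clip_ids=(sa.clip_id, sb.clip_id))
            row = _base_row(sa, sb, method, rep.overall_similarity, rep.overall_DS)
            for name, ds in rep.per_phase_DS().items():
                row[f"ds_{name}"] = ds
            rows.append(row)
    else:
        usable = []
        for seq in clips:
            try:
                preprocess_sequence(seq, cfg.preprocess)
                usable.append(seq)
            except DmsmError as exc:
                logger.warning("clip %s excluded: %s", seq.clip_id, exc)
                failures.append((seq.clip_id, str(exc)))
        for sa, sb in itertools.combinations(usable, 2):
            try:
                sim, ds, _ = compare(sa, sb, method, cfg)
            except DmsmError as exc:
                logger.warning("pair (%s, %s) excluded: %s", sa.clip_id, sb.clip_id, exc)
                failures.append((f"{sa.clip_id}|{sb.clip_id}", str(exc)))
                continue
            rows.append(_base_row(sa, sb, method, sim, ds))

    columns = ["clip_a", "clip_b", "player_a", "player_b", "method",
               "similarity", "DS", "pair_class"]
    if method == "dmsm":
        columns += [f"ds_{n}" for n in PHASE_NAMES]
    return EvalTable(pd.DataFrame(rows, columns=columns), method, failures)


def _base_row(sa: PoseSequence, sb: PoseSequence, method: str, sim: float, ds: float) -> dict:
    return {
        "clip_a": sa.clip_id,
        "clip_b": sb.clip_id,
        "player_a": sa.player_id,
        "player_b": sb.player_id,
        "method": method,
        "similarity": sim,
        "DS": ds,
        "pair_class": "same_player" if sa.player_id == sb.player_id else "cross_player",
    }


def separation_statistics(
    table: EvalTable,
    n_bootstrap: int = 2000,
    seed: int = 0,
    column: str = "DS",
) -> SeparationStats:
    """Class-separation statistics on the chosen column (default DS).

    Separation = mean(cross) − mean(same); Welch's t because the classes are
    independent samples of unequal size and variance; percentile bootstrap
    for the CI (seeded, reproducible).
    """
    if n_bootstrap < 100:
        raise ParameterError("n_bootstrap must be >= 100")
    same, cross = table.values_by_class(column)
    if len(same) == 0 or len(cross) == 0:
        raise ParameterError(
            "separation needs at least one same-player and one cross-player pair"
        )
    return _separation_from_arrays(same, cross, n_bootstrap, seed)


def _separation_from_arrays(
    same: np.ndarray, cross: np.ndarray, n_bootstrap: int, seed: int
) -> SeparationStats:
    mean_same, mean_cross = float(np.mean(same)), float(np.mean(cross))
    sep = mean_cross - mean_same
    t_res = stats.ttest_ind(cross, same, equal_var=False)

    def shapiro_or_none(v: np.ndarray) -> float | None:
        if len(v) < 3:
            logger.warning("class with %d values: Shapiro-Wilk skipped", len(v))
            return None
        return float(stats.shapiro(v).pvalue)

    n1, n2 = len(same), len(cross)
    pooled = np.sqrt(
        ((n1 - 1) * np.var(same, ddof=1) + (n2 - 1) * np.var(cross, ddof=1))
        / max(n1 + n2 - 2, 1)
    )
    d = sep / pooled if pooled > 0 else 0.0

    rng = np.random.default_rng(seed)
    reps = np.empty(n_bootstrap)
    for k in range(n_bootstrap):
        reps[k] = np.mean(rng.choice(cross, n2)) - np.mean(rng.choice(same, n1))
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return SeparationStats(
        mean_same=mean_same,
        mean_cross=mean_cross,
        separation=sep,
        t_statistic=float(t_res.statistic),
        p_value=float(t_res.pvalue),
        shapiro_p=(shapiro_or_none(same), shapiro_or_none(cross)),
        cohens_d=float(d),
        bootstrap_ci_95=(float(lo), float(hi)),
        n_same=n1,
        n_cross=n2,
    )


@dataclass
class MethodComparison:
    tables: dict[str, EvalTable]
    separations: dict[str, SeparationStats]
    paired_vs_first: dict[str, tuple[float, float]]
    reference_method: str

    def summary(self) -> pd.DataFrame:
        rows = []
        for m, tab in self.tables.items():
            sims = tab.df["similarity"].to_numpy()
            sep = self.separations[m]
            t_p = self.paired_vs_first.get(m)
            rows.append(
                {
                    "method": m,
                    "mean_similarity": float(np.mean(sims)),
                    "sd_similarity": float(np.std(sims, ddof=1)),
                    "separation": sep.separation,
                    "p_separation": sep.p_value,
                    "cohens_d": sep.cohens_d,
                    "p_vs_reference": t_p[1] if t_p else np.nan,
                }
            )
        return pd.DataFrame(rows)


def method_comparison(
    source: ClipManifest | list[PoseSequence],
    methods: list[str],
    cfg: SimilarityConfig | None = None,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> MethodComparison:
    """Run several methods on identical pair lists and contrast them.

    Per-pair similarities are paired across methods (same clip pairs), so the
    method-vs-method test is a paired t-test against the first method.
    """
    if len(methods) < 1:
        raise ParameterError("need at least one method")
    cfg = cfg or SimilarityConfig()
    clips = _load_clips(source)
    tables, separations = {}, {}
    for m in methods:
        tab = pairwise_evaluation(clips, m, cfg)
        tables[m] = tab
        separations[m] = separation_statistics(tab, n_bootstrap, seed)
    ref = methods[0]
    ref_df = tables[ref].df.set_index(["clip_a", "clip_b"])
    paired = {}
    for m in methods[1:]:
        df = tables[m].df.set_index(["clip_a", "clip_b"])
        common = ref_df.index.intersection(df.index)
        if len(common) < 2:
            paired[m] = (np.nan, np.nan)
            continue
        res = stats.ttest_rel(
            ref_df.loc[common, "similarity"], df.loc[common, "similarity"]
        )
        paired[m] = (float(res.statistic), float(res.pvalue))
    return MethodComparison(tables, separations, paired, ref)


def synthetic_benchmark(
    n_styles: int = 8,
    clips_per_style: int = 4,
    seed: int = 0,
    within_player_sd: float = 0.05,
    fps: float = 30.0,
) -> list[PoseSequence]:
    """Seeded bank of synthetic players: one base style per synthetic player,
    ``clips_per_style`` repeats each; the default scale mirrors a small
    practice-range dataset."""
    rng = np.random.default_rng(seed)
    clips = []
    for s in range(n_styles):
        base = random_style(rng)
        player = f"style{s:02d}"
        for clip in sample_player(
            base, clips_per_style, within_player_sd,
            seed=int(rng.integers(2**31)), fps=fps, player_id=player,
        ):
            clips.append(clip.sequence)
    return clips
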