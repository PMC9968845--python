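"""End-to-end study orchestration and reporting.

``run_study`` drives the full pipeline on a synthetic cohort: generate ->
preprocess -> per-session ERD/ERS table -> cross-train/test matrices ->
per-cell distribution statistics -> training-set strategy evaluation.
Every tabular artifact is a plain CSV; a manifest records the
configuration, the seed and a checksum per file, and reruns with the
same seed are byte-identical.

The multi-subject design ("exp1", 8 subjects x 1 session) yields one
8x8 matrix and a cross-subject strategy table; the multi-session design
("exp2") yields a 10x10 matrix and a cross-session strategy table per
subject.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .preprocess import (CLASSIFY_WINDOW, TFR_WINDOW, EpochSet,
                         preprocess_chain)
from .strategies import StrategyReport, evaluate_strategies
from .synthgen import CohortConfig, SessionRecording, exp1_config, exp2_config, make_cohort
from .tfa import erd_ers_index, wavelet_tfr
from .xfer_stats import (CrossMatrix, TTestReport, build_cross_matrix,
                         compare_exp_groups, dist_stats)
from .csp import fit_csp_from_epochs, extract_features
from .lda import fit_lda, predict, accuracy

__all__ = ["StudyConfig", "StudyResult", "run_study", "replay_online_split",
           "stage_seed", "compare_studies", "load_study_config"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2^31) from one global seed."""
    return (seed * 2654435761 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class StudyConfig:
    """One study design plus analysis settings."""

    preset: str = "exp1"                  # exp1 | exp2 | custom
    seed: int = 0
    cohort: CohortConfig | None = None    # required for preset="custom"
    n_subjects_exp2: int = 1              # paper-shaped runs use 2
    n_pairs_analysis: int = 1
    n_pairs_online: int = 3
    run_tfa: bool = True
    run_crossmat: bool = True
    run_stats: bool = True
    run_strategies: bool = True
    out_dir: str = "study_out"
    #: size overrides for scaled-down cohorts (None = paradigm defaults)
    n_runs: int | None = None
    trials_per_run: int | None = None

    def cohort_config(self) -> CohortConfig:
        over = {}
        if self.n_runs is not None:
            over["n_runs"] = self.n_runs
        if self.trials_per_run is not None:
            over["trials_per_run"] = self.trials_per_run
        if self.preset == "exp1":
            return exp1_config(seed=stage_seed(self.seed, "cohort"), **over)
        if self.preset == "exp2":
            return exp2_config(seed=stage_seed(self.seed, "cohort"),
                               n_subjects=self.n_subjects_exp2, **over)
        if self.preset == "custom":
            if self.cohort is None:
                raise ValueError("custom preset needs an explicit CohortConfig")
            return self.cohort
        raise ValueError(f"unknown preset {self.preset!r}")


@dataclass
class StudyResult:
    config: StudyConfig
    erd_table: pd.DataFrame | None
    matrices: dict[str, CrossMatrix]
    stats_tables: dict[str, pd.DataFrame]
    strategy_reports: dict[str, StrategyReport]
    out_dir: Path
    manifest: dict


def load_study_config(path: str | Path) -> StudyConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort = raw.pop("cohort", None)
    cfg = StudyConfig(**raw)
    if cohort is not None:
        cfg.cohort = CohortConfig(**cohort)
    return cfg


def _erd_rows(sessions: list[EpochSet]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for code, hand in ((1, "left"), (2, "right")):
            tfr = wavelet_tfr(s, class_label=code, channels=["C3", "C4"])
            for ch in ("C3", "C4"):
                rep = erd_ers_index(tfr, ch)
                side = ("contra" if (hand == "left") == (ch == "C4")
                        else "ipsi")
                rows.append({"subject": s.subject_id, "session": s.session_id,
                             "class": hand, "channel": ch, "side": side,
                             "p_pre": rep.p_pre, "p_post": rep.p_post,
                             "erd_index_pct": rep.index})
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path, manifest: dict,
               float_format: str = "%.6g") -> None:
    df.to_csv(path, float_format=float_format)
    manifest["files"][path.name] = hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(config: StudyConfig) -> StudyResult:
    """Run every enabled stage and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ccfg = config.cohort_config()
    manifest = {"config": dataclasses.asdict(dataclasses.replace(
        config, cohort=None)),
        "cohort_config": {k: (list(v) if isinstance(v, tuple) else v)
                          for k, v in dataclasses.asdict(ccfg).items()},
        "seed": config.seed, "version": __version__, "files": {}}

    recordings = make_cohort(ccfg)
    classify = [preprocess_chain(r, window=CLASSIFY_WINDOW) for r in recordings]

    erd_table = None
    if config.run_tfa:
        tfr_epochs = [preprocess_chain(r, window=TFR_WINDOW) for r in recordings]
        erd_table = _erd_rows(tfr_epochs)
        _write_csv(erd_table.set_index(["subject", "session"]),
                   out / "erd_indices.csv", manifest)

    matrices: dict[str, CrossMatrix] = {}
    stats_tables: dict[str, pd.DataFrame] = {}
    if config.run_crossmat:
        groups: dict[str, list[EpochSet]]
        if config.preset == "exp1" or ccfg.n_sessions_per_subject == 1:
            # one matrix across subjects; label cells by subject
            sess = [dataclasses.replace(s, session_id=s.subject_id)
                    for s in classify]
            groups = {"cross_subject": sess}
        else:
            groups = {}
            for sid in dict.fromkeys(s.subject_id for s in classify):
                groups[sid] = [s for s in classify if s.subject_id == sid]
        for name, sess in groups.items():
            mat = build_cross_matrix(sess, n_pairs=config.n_pairs_analysis)
            matrices[name] = mat
            _write_csv(mat.accuracy_frame(), out / f"crossmat_{name}.csv",
                       manifest)
            if config.run_stats:
                rows = []
                for i in range(mat.m):
                    for j in range(mat.m):
                        d = dist_stats(mat.feats[i][j])
                        rows.append({"train": mat.session_ids[i],
                                     "test": mat.session_ids[j],
                                     "cell": "diag" if i == j else "offdiag",
                                     **d.as_row()})
                df = pd.DataFrame(rows).set_index(["train", "test"])
                stats_tables[name] = df
                _write_csv(df, out / f"dist_stats_{name}.csv", manifest)

    strategy_reports: dict[str, StrategyReport] = {}
    if config.run_strategies:
        if config.preset == "exp1" or ccfg.n_sessions_per_subject == 1:
            sess = [dataclasses.replace(s, session_id=s.subject_id)
                    for s in classify]
            rep = evaluate_strategies(sess, task="cross-subject",
                                      n_pairs=config.n_pairs_analysis)
            strategy_reports["cross_subject"] = rep
            _write_csv(rep.to_frame(), out / "strategies_cross_subject.csv",
                       manifest)
        else:
            for sid in dict.fromkeys(s.subject_id for s in classify):
                sess = [s for s in classify if s.subject_id == sid]
                rep = evaluate_strategies(sess, task="cross-session",
                                          n_pairs=config.n_pairs_analysis)
                strategy_reports[sid] = rep
                _write_csv(rep.to_frame(), out / f"strategies_{sid}.csv",
                           manifest)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return StudyResult(config=config, erd_table=erd_table, matrices=matrices,
                       stats_tables=stats_tables,
                       strategy_reports=strategy_reports, out_dir=out,
                       manifest=manifest)


def compare_studies(mat_a: list[CrossMatrix], mat_b: list[CrossMatrix],
                    which: str = "offdiag", family_alpha: float = 0.05,
                    n_comparisons: int = 12) -> TTestReport:
    """Pool DistStats of the given cells across each study's matrices and
    t-test the two studies per statistic (Bonferroni-adjusted)."""
    stats_a = [d for m in mat_a for d in m.cell_stats(which)]
    stats_b = [d for m in mat_b for d in m.cell_stats(which)]
    return compare_exp_groups(stats_a, stats_b, family_alpha=family_alpha,
                              n_comparisons=n_comparisons)


def replay_online_split(session: EpochSet, n_pairs: int = 3) -> float:
    """Train on the first half of runs, test on the last half.

    Mirrors an online protocol where the opening runs calibrate the
    decoder; with the standard 8 runs this is runs 1-4 vs runs 5-8.
    Returns percent accuracy on the held-out runs.
    """
    if session.runs is None:
        raise ValueError("session has no run structure")
    runs = np.unique(session.runs)
    if len(runs) < 2:
        raise ValueError("need at least 2 runs to split")
    train_runs = runs[:len(runs) // 2]
    train_mask = np.isin(session.runs, train_runs)
    train = EpochSet(trials=session.trials[train_mask],
                     labels=session.labels[train_mask],
                     time_axis=session.time_axis, fs=session.fs,
                     channel_labels=session.channel_labels,
                     runs=session.runs[train_mask],
                     subject_id=session.subject_id,
                     session_id=session.session_id)
    test_mask = ~train_mask
    model = fit_csp_from_epochs(train, n_pairs=n_pairs)
    lda = fit_lda(extract_features(model, train))
    f = extract_features(model, EpochSet(
        trials=session.trials[test_mask], labels=session.labels[test_mask],
        time_axis=session.time_axis, fs=session.fs,
        channel_labels=session.channel_labels, runs=session.runs[test_mask],
        subject_id=session.subject_id, session_id=session.session_id))
    return accuracy(predict(lda, f), f.labels)
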