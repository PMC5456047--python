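"""End-to-end study orchestration at desk scale.

``simulate_study`` generates a full synthetic study (dyads x two
conversations, four condition cells); ``run_study`` computes the
real-pair and virtual-pair coordination metrics tables, calibrates the
CRQA radius globally, and runs both predictions; ``run_all`` adds tidy
CSV/JSON/figure outputs plus a provenance log and is fully
deterministic given the global seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .core import UniformSeries
from .crqa import EmbeddingParams, calibrate_radius
from .predict import CvPredictionResult, build_features, cv_predict
from .records import (ConversationRecord, DyadRecord, analyze_pair,
                      flatten_conversations, metrics_row)
from .simulate import (ConditionEffects, MovementSimParams, SpeechSimParams,
                       generate_movement_pair, generate_speech_pair)
from .speech import rate_series
from .surrogates import make_virtual_pairs, plan_to_frame, surrogate_metrics
from .wlcc import WlccParams

logger = logging.getLogger("dyadsync")

__all__ = ["StudyParams", "RunConfig", "simulate_study", "run_study",
           "run_all", "real_metrics"]

SEX_COMPOSITIONS = ("female-female", "male-male", "mixed")


@dataclass(frozen=True)
class StudyParams:
    """Synthetic-study design: sizes, channel defaults, condition effects.

    ``lower_gain`` is the fixed (condition-independent) coupling of the
    lower-body control channel; conditions modulate head coupling and
    speech-rate matching only, through ``effects``.
    """

    n_dyads: int = 20
    duration_s: float = 480.0
    movement: MovementSimParams = field(
        default_factory=lambda: MovementSimParams())
    speech: SpeechSimParams = field(default_factory=lambda: SpeechSimParams())
    effects: ConditionEffects = field(default_factory=ConditionEffects)
    lower_gain: float = 0.15


@dataclass(frozen=True)
class RunConfig:
    """Everything a full run needs; round-trips to YAML/JSON."""

    study: StudyParams = field(default_factory=StudyParams)
    wlcc: WlccParams = field(default_factory=WlccParams)
    embedding: EmbeddingParams = field(default_factory=EmbeddingParams)
    target_rr: float = 0.05
    calibrate: bool = True
    n_surrogate_plans: int = 1
    predict_repeats: int = 100
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["study"]["effects"] = {
            f"{v}/{c}": asdict(cell)
            for (v, c), cell in self.study.effects.cells.items()}
        return d


def _subseed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def simulate_study(params: StudyParams, seed: int = 0) -> list[DyadRecord]:
    """Generate a full synthetic study, deterministic given ``seed``.

    Half the dyads are assigned to the disagree condition.  Each dyad
    holds two conversations (deception/truth, order counterbalanced by
    a seeded draw); head movement and speech-rate matching follow the
    dyad's condition cell, the lower-body channel uses the fixed
    control coupling.
    """
    root = np.random.SeedSequence(seed)
    assign_rng = np.random.default_rng(_subseed(root))
    dataset: list[DyadRecord] = []
    for di in range(params.n_dyads):
        conflict = "disagree" if di < (params.n_dyads + 1) // 2 else "agree"
        sex = SEX_COMPOSITIONS[int(assign_rng.integers(len(SEX_COMPOSITIONS)))]
        veracity_order = (["deception", "truth"]
                          if assign_rng.random() < 0.5
                          else ["truth", "deception"])
        dyad = DyadRecord(dyad_id=f"d{di:03d}", conflict=conflict,
                          sex_composition=sex)
        for order, veracity in enumerate(veracity_order, start=1):
            cell = params.effects[(veracity, conflict)]
            conv_ss = root.spawn(1)[0]
            head_seed, lower_seed, speech_seed = (
                _subseed(s) for s in conv_ss.spawn(3))

            mv = replace(params.movement, duration_s=params.duration_s,
                         coupling_gain=cell.coupling_gain,
                         coupling_lag_s=cell.coupling_lag_s, seed=head_seed)
            head_naive, head_da = generate_movement_pair(mv)
            mv_low = replace(mv, coupling_gain=params.lower_gain,
                             coupling_lag_s=0.0, seed=lower_seed)
            lower_naive, lower_da = generate_movement_pair(mv_low)

            sp = replace(params.speech, duration_s=params.duration_s,
                         matching_c=cell.matching_c, seed=speech_seed)
            speech = generate_speech_pair(sp)
            span = (0.0, params.duration_s)
            # speaker A plays the DA role throughout
            rate_da = rate_series(speech.events_a, span)
            rate_naive = rate_series(speech.events_b, span)

            dyad.conversations.append(ConversationRecord(
                dyad_id=dyad.dyad_id,
                conversation_id=f"{dyad.dyad_id}_c{order}",
                veracity=veracity, conflict=conflict, order=order,
                sex_composition=sex,
                head_da=head_da, head_naive=head_naive,
                lower_da=lower_da, lower_naive=lower_naive,
                rate_da=rate_da, rate_naive=rate_naive,
                raw={"speech": speech},
            ))
        dyad.validate()
        dataset.append(dyad)
    return dataset


def real_metrics(dataset: list[DyadRecord],
                 wlcc_params: WlccParams = WlccParams(),
                 emb_params: EmbeddingParams = EmbeddingParams()) -> pd.DataFrame:
    """Coordination metrics for every real conversation pair."""
    rows = []
    for conv in flatten_conversations(dataset):
        metrics = analyze_pair(conv.head_da, conv.head_naive,
                               conv.lower_da, conv.lower_naive,
                               conv.rate_da, conv.rate_naive,
                               wlcc_params, emb_params)
        rows.append(metrics_row(conv, "real", metrics))
    return pd.DataFrame(rows)


def calibrated_embedding(dataset: list[DyadRecord], config: RunConfig
                         ) -> EmbeddingParams:
    """Globally calibrate the CRQA radius on the real speech-rate pairs."""
    if not config.calibrate:
        return config.embedding
    pairs = [(c.rate_da, c.rate_naive) for c in flatten_conversations(dataset)
             if c.rate_da is not None and np.std(c.rate_da.values) > 0
             and np.std(c.rate_naive.values) > 0]
    eps = calibrate_radius(pairs, config.embedding, target_rr=config.target_rr)
    logger.info("calibrated CRQA radius: %.4f (target RR %.3f)",
                eps, config.target_rr)
    return replace(config.embedding, radius=eps)


@dataclass
class StudyResult:
    metrics: pd.DataFrame            # real + virtual rows
    features: pd.DataFrame
    predictions: dict[str, CvPredictionResult]
    embedding: EmbeddingParams
    plans: list[Any]


def run_study(dataset: list[DyadRecord], config: RunConfig) -> StudyResult:
    """Metrics (real and virtual), features, and both predictions."""
    emb = calibrated_embedding(dataset, config)
    real = real_metrics(dataset, config.wlcc, emb)

    plan_rng = np.random.default_rng(np.random.SeedSequence(
        (config.seed, 0x5a11)).generate_state(1)[0] % (2**31 - 1))
    plans, virtual_tables = [], []
    for _ in range(config.n_surrogate_plans):
        plan = make_virtual_pairs(dataset, int(plan_rng.integers(2**31 - 1)))
        plans.append(plan)
        virtual_tables.append(surrogate_metrics(dataset, plan,
                                                config.wlcc, emb))
    metrics = pd.concat([real] + virtual_tables, ignore_index=True)

    features = build_features(real)
    predictions = {}
    for label in ("veracity", "conflict"):
        try:
            predictions[label] = cv_predict(
                features, label=label, n_repeats=config.predict_repeats,
                seed=config.seed)
        except Exception as exc:  # e.g. too few dyads in a tiny test run
            logger.warning("prediction for %s skipped: %s", label, exc)
    return StudyResult(metrics=metrics, features=features,
                       predictions=predictions, embedding=emb, plans=plans)


def _profile_figure(dataset: list[DyadRecord], config: RunConfig,
                    emb, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from .wlcc import lag_profile

    cells = sorted({c.condition for c in flatten_conversations(dataset)})
    fig, axes = plt.subplots(1, len(cells), figsize=(4 * len(cells), 3.2),
                             sharey=True, squeeze=False)
    for ax, cond in zip(axes[0], cells):
        profs = []
        for c in flatten_conversations(dataset):
            if c.condition != cond:
                continue
            p = lag_profile(c.head_da, c.head_naive, config.wlcc)
            ax.plot(p.lags_s * 1000, p.r_mean, color="0.8", lw=0.6)
            profs.append(p.r_mean)
        if profs:
            mean = np.nanmean(np.vstack(profs), axis=0)
            ax.plot(p.lags_s * 1000, mean, color="C3", lw=2)
        ax.axvline(0, color="0.5", ls=":")
        ax.set_title(f"{cond[0]} / {cond[1]}", fontsize=9)
        ax.set_xlabel("lag (ms)")
    axes[0][0].set_ylabel("mean windowed r")
    fig.suptitle("Head-movement WLCC profiles (grey: dyads; red: mean)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _crqa_figure(metrics: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    indices = ["RR", "DET", "L", "LMAX", "T2", "ENTR"]
    real = metrics[metrics.pairing_type == "real"]
    fig, axes = plt.subplots(2, 3, figsize=(10, 5.5))
    for ax, idx in zip(axes.ravel(), indices):
        means = real.groupby(["veracity", "conflict"])[idx].mean()
        means.plot.bar(ax=ax, color="C0")
        ax.set_title(idx, fontsize=9)
        ax.tick_params(axis="x", labelrotation=45, labelsize=6)
        ax.set_xlabel("")
    fig.suptitle("Speech-rate CRQA indices by condition (real pairs)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_all(config: RunConfig, outdir: str | Path) -> StudyResult:
    """Simulate, analyze, predict, and write the full report bundle.

    Writes metrics.csv (real + virtual rows), features.csv, pairing
    plan CSVs, predictions.json, two figures, and provenance.json with
    every parameter and seed.  Byte-identical outputs for identical
    config + seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = simulate_study(config.study, seed=config.seed)
    result = run_study(dataset, config)

    result.metrics.to_csv(outdir / "metrics.csv", index=False,
                          float_format="%.10g")
    result.features.to_csv(outdir / "features.csv", index=False,
                           float_format="%.10g")
    for i, plan in enumerate(result.plans):
        plan_to_frame(plan).to_csv(outdir / f"pairing_plan_{i}.csv",
                                   index=False)
    with open(outdir / "predictions.json", "w") as fh:
        json.dump({k: v.as_dict() for k, v in result.predictions.items()},
                  fh, indent=2, sort_keys=True)
    with open(outdir / "provenance.json", "w") as fh:
        prov = config.to_dict()
        prov["embedding_used"] = asdict(result.embedding)
        prov["n_conversations"] = int(
            (result.metrics.pairing_type == "real").sum())
        json.dump(prov, fh, indent=2, sort_keys=True, default=str)

    _profile_figure(dataset, config, result.embedding,
                    outdir / "wlcc_profiles.png")
    _crqa_figure(result.metrics, outdir / "crqa_condition_means.png")
    return result
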