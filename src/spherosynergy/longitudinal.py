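"""Per-day synergy trajectories and the end-to-end pipeline.

A trajectory is the ordered sequence of synergy scores for one
(pair, cell line, method) across imaging days — the longitudinal readout
the whole package exists to produce.  No smoothing or trend fitting is
applied: days excluded by the missing-data rules are simply absent.

:func:`run_pipeline` wires every stage together for a simulated study:
generate images -> preprocess -> train the decoder on endpoint labels ->
predict viability for all days -> normalize per plate/day -> synergy
surfaces per day -> trajectories, and writes the tidy CSV outputs plus a
summary plot and a seeded run log.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import decode, imgprep, simulate, synergy
from .study_design import StudyDesign, desk_design

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "PipelineConfig",
    "build_trajectories",
    "compare_endpoint",
    "run_pipeline",
]


@dataclass(frozen=True)
class Trajectory:
    pair: str
    cell_line: str
    method: str
    days: tuple[int, ...]
    scores: tuple[float, ...]
    endpoint_observed_score: float | None = None

    def __post_init__(self) -> None:
        if len(self.days) != len(self.scores):
            raise ValueError("days and scores must align")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")


def build_trajectories(
    results: Sequence[synergy.SynergyResult],
    endpoint_observed: Sequence[synergy.SynergyResult] = (),
) -> list[Trajectory]:
    """Group synergy results into per-(pair, line, method) day series.

    ``endpoint_observed`` optionally supplies assay-derived endpoint scores
    to attach to each trajectory.  Duplicate (pair, line, method, day)
    entries are an error; missing days are simply gaps.
    """
    obs_lookup = {
        (r.pair, r.cell_line, r.method): r.score for r in endpoint_observed
    }
    grouped: dict[tuple[str, str, str], dict[int, float]] = {}
    for r in results:
        key = (r.pair, r.cell_line, r.method)
        per_day = grouped.setdefault(key, {})
        if r.day in per_day:
            raise ValueError(f"duplicate synergy result for {key} day {r.day}")
        per_day[r.day] = r.score
    out = []
    for key in sorted(grouped):
        pair, line, method = key
        days = tuple(sorted(grouped[key]))
        out.append(
            Trajectory(
                pair=pair,
                cell_line=line,
                method=method,
                days=days,
                scores=tuple(grouped[key][d] for d in days),
                endpoint_observed_score=obs_lookup.get(key),
            )
        )
    return out


def compare_endpoint(
    predicted: Sequence[synergy.SynergyResult],
    observed: Sequence[synergy.SynergyResult],
) -> decode.FitMetrics:
    """Regress observed endpoint synergy scores on predicted ones.

    Pairs results by (pair, cell line, method); requires >= 3 shared
    samples.  Same OLS machinery (adjusted R², slope p-value) as the
    viability evaluation.
    """
    pred_map = {(r.pair, r.cell_line, r.method): r.score for r in predicted}
    obs_map = {(r.pair, r.cell_line, r.method): r.score for r in observed}
    shared = sorted(set(pred_map) & set(obs_map))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 paired samples, got {len(shared)}")
    return decode.evaluate_predictions(
        [pred_map[k] for k in shared], [obs_map[k] for k in shared]
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one simulated end-to-end run needs.

    The desk-scale defaults (1 cell line, 4 pairs, 2 replicates, 64 px
    images) finish on a laptop CPU in a few minutes; raise
    ``n_cell_lines/n_pairs`` and ``image_size`` toward 3/16/224 to mirror
    the full screen.
    """

    n_cell_lines: int = 1
    n_pairs: int = 4
    n_replicates: int = 2
    image_size: int = 64
    synergy_alpha: float = 0.0
    noise_sd: float = 5.0
    n_empty_wells: int = 8
    train_pair_fraction: float = 0.5  # pairs assigned to the training pool
    methods: tuple[str, ...] = ("LOEWE", "BLISS", "HSA")
    net: decode.NetConfig | None = None
    seed: int = 0

    def design(self) -> StudyDesign:
        return desk_design(self.n_cell_lines, self.n_pairs, self.n_replicates)

    def net_config(self) -> decode.NetConfig:
        if self.net is not None:
            return self.net
        return decode.NetConfig(input_size=self.image_size,
                                train_seed=self.seed)


def _load_image_set(data_dir: Path, cfg: imgprep.PreprocessConfig) -> decode.ImageSet:
    meta = pd.read_csv(data_dir / "metadata.csv")
    images = imgprep.preprocess_batch(
        [data_dir / "images" / f for f in meta["filename"]], cfg
    )
    return decode.ImageSet(images, meta)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute simulate -> preprocess -> train -> predict -> synergy.

    Writes, under ``out_dir``: the simulated dataset, ``predictions.csv``
    (raw + per-day-normalized viability), ``synergy.csv`` (one row per
    pair/line/day/method for predicted and endpoint-observed scores),
    ``trajectories.csv``, ``history.csv`` (training losses),
    ``metrics.json`` and ``run_log.json`` (seeds, sizes, versions), and a
    trajectory summary plot.  Returns the bundle as a dict of DataFrames /
    metric objects.  Fully deterministic given ``config.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design()
    stage = "simulate"
    try:
        data_dir = out / "dataset"
        responses = simulate.default_response_params(design, config.synergy_alpha)
        simulate.generate_dataset(
            design,
            data_dir,
            responses=responses,
            render_params=simulate.RenderParams(image_size=config.image_size),
            noise_sd=config.noise_sd,
            n_empty_wells=config.n_empty_wells,
            seed=config.seed,
        )

        stage = "preprocess"
        # Synthetic renders are already margin-free, and the spheroid's
        # absolute size carries the viability signal: keep a fixed
        # full-frame window (consistent across days) instead of the
        # per-spheroid adaptive zoom used for real microscope frames.
        prep_cfg = imgprep.PreprocessConfig(
            output_size=config.net_config().input_size, min_crop_frac=1.0
        )
        data = _load_image_set(data_dir, prep_cfg)
        labels = pd.read_csv(data_dir / "labels.csv")
        truth = pd.read_csv(data_dir / "ground_truth.csv")

        stage = "split+train"
        pair_names = [p.name for p in design.drug_pairs]
        n_train = max(int(round(config.train_pair_fraction * len(pair_names))), 1)
        split = decode.SplitSpec(
            train_pairs=tuple(pair_names[:n_train]), split_seed=config.seed
        )
        label_map = dict(zip(labels["filename"], labels["viability_pct"]))
        endpoint_mask = data.meta["filename"].isin(label_map).to_numpy()
        endpoint_set = data.subset(endpoint_mask)
        endpoint_set.meta["viability_pct"] = endpoint_set.meta["filename"].map(label_map)
        train_set, val_set, test_set = decode.split_dataset(endpoint_set, split)
        model, history = decode.train_model(train_set, val_set, config.net_config())

        stage = "predict+normalize"
        raw = decode.predict_viability(model, data.images)
        pred = data.meta.copy()
        pred["raw_pred"] = raw
        pred = pred[pred["plate_id"] != "empty"]
        pred = decode.normalize_per_day(pred)
        pred["test_pair"] = ~pred["pair"].isin(split.train_pairs)

        stage = "synergy"
        pred_mats = synergy.matrices_from_viability(pred, provenance="predicted")
        pred_results = synergy.compute_all(pred_mats, config.methods)
        obs_endpoint = truth[
            (truth["day"] == design.endpoint_day) & (truth["plate_id"] != "empty")
        ]
        obs_mats = synergy.matrices_from_viability(
            obs_endpoint, value_column="measured_viability_pct", provenance="measured"
        )
        obs_results = synergy.compute_all(obs_mats, config.methods)

        stage = "trajectories+metrics"
        trajectories = build_trajectories(pred_results, obs_results)
        synergy_rows = [
            {
                "pair": r.pair, "cell_line": r.cell_line, "day": r.day,
                "method": r.method, "provenance": r.provenance,
                "score": r.score, "volume": r.volume,
                "n_wells": r.n_wells_used, "flags": ";".join(r.flags),
            }
            for r in pred_results + obs_results
        ]
        synergy_df = pd.DataFrame(synergy_rows)
        traj_df = pd.DataFrame(
            [
                {
                    "pair": t.pair, "cell_line": t.cell_line, "method": t.method,
                    "day": d, "score": s,
                    "endpoint_observed_score": t.endpoint_observed_score,
                }
                for t in trajectories
                for d, s in zip(t.days, t.scores)
            ]
        )

        metrics: dict[str, object] = {}
        test_endpoint = pred[
            (pred["day"] == design.endpoint_day) & pred["test_pair"]
        ].merge(
            truth[truth["day"] == design.endpoint_day][
                ["filename", "true_viability_pct", "measured_viability_pct"]
            ],
            on="filename",
        )
        # Replicate-mean rule before regression.
        rep_mean = (
            test_endpoint.groupby(["pair", "cell_line", "row", "col"])
            .agg(pred=("viability_pct", "mean"), true=("true_viability_pct", "mean"),
                 measured=("measured_viability_pct", "mean"))
            .reset_index()
        )
        fit_true = decode.evaluate_predictions(rep_mean["pred"], rep_mean["true"])
        fit_meas = decode.evaluate_predictions(rep_mean["pred"], rep_mean["measured"])
        metrics["endpoint_adj_r2_vs_truth"] = fit_true.adj_r_squared
        metrics["endpoint_adj_r2_vs_assay"] = fit_meas.adj_r_squared
        try:
            syn_fit = compare_endpoint(pred_results, obs_results)
            metrics["endpoint_synergy_adj_r2"] = syn_fit.adj_r_squared
            metrics["endpoint_synergy_slope"] = syn_fit.slope
        except ValueError:
            metrics["endpoint_synergy_adj_r2"] = None

        stage = "write"
        pred.to_csv(out / "predictions.csv", index=False)
        synergy_df.to_csv(out / "synergy.csv", index=False)
        traj_df.to_csv(out / "trajectories.csv", index=False)
        history.to_csv(out / "history.csv", index=False)
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
        (out / "run_log.json").write_text(
            json.dumps(
                {
                    "seed": config.seed,
                    "package_version": __version__,
                    "python": platform.python_version(),
                    "numpy": np.__version__,
                    "n_images": len(data),
                    "n_train": len(train_set),
                    "n_val": len(val_set),
                    "n_test": len(test_set),
                    "n_synergy_results": len(pred_results),
                    "stage_order": [
                        "simulate", "preprocess", "split+train",
                        "predict+normalize", "synergy", "trajectories+metrics",
                    ],
                },
                indent=2,
            )
        )
        _plot_trajectories(traj_df, out / "trajectories.png")
    except Exception as exc:  # annotate which stage broke, then re-raise
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    return {
        "design": design,
        "model": model,
        "history": history,
        "predictions": pred,
        "synergy": synergy_df,
        "trajectories": trajectories,
        "trajectory_table": traj_df,
        "metrics": metrics,
    }


def _plot_trajectories(traj_df: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if traj_df.empty:
        return
    methods = sorted(traj_df["method"].unique())
    fig, axes = plt.subplots(
        1, len(methods), figsize=(4 * len(methods), 3.2), squeeze=False, sharey=True
    )
    for ax, method in zip(axes[0], methods):
        sub = traj_df[traj_df["method"] == method]
        for (pair, line), grp in sub.groupby(["pair", "cell_line"]):
            ax.plot(grp["day"], grp["score"], marker="o", label=f"{pair} {line}")
            obs = grp["endpoint_observed_score"].dropna()
            if len(obs):
                ax.plot(grp["day"].max(), obs.iloc[0], marker="s", color="black")
        ax.axhline(0.0, color="gray", lw=0.7)
        ax.set_title(method)
        ax.set_xlabel("day")
    axes[0][0].set_ylabel("synergy score (% viability)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
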