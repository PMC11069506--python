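"""End-to-end, seeded experiment harness on synthetic M-scans.

Four studies mirror the standard evaluation of a short-trace amplitude
predictor:

``phantom``
    Simulate in-focus and out-of-focus phantom cubes, train the network on a
    lateral training region of both, reconstruct GT / ST / NET images on the
    held-out region and tabulate contrast, MSE and SSIM.
``cycle_group``
    Split an 18-cycle record into 9 consecutive two-cycle groups, train one
    network per group and cross-test every network on every group — probes
    how strongly the predictor keys on the bulk-heating transient.
``cross_sample``
    Three synthetic "sample types" with distinct parameter distributions;
    per-type networks plus one pooled network, cross-tested (4 x 3 matrix).
``input_length``
    Sweep the input length over a grid of modulation cycle counts with the
    deeper [n, 40, 20, 5, 1] architecture, comparing network MSE against the
    conventional short-trace reconstruction of the same length.

Every study is a pure function of (config, seed): identical inputs give
byte-identical reports.  Default problem sizes are desk scale — pools of a
few thousand to twenty thousand pairs and a few tens of epochs — so each
study completes in minutes on one CPU.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as _io
from .lockin import (
    extract_training_pairs,
    lockin_amplitude_array,
    intensity_mask,
    reconstruct_image,
    reference_trace,
)
from .metrics import MetricsReport, metrics_report, regions_from_labels
from .ptnet import (
    FoldResult,
    NetworkConfig,
    NetworkParams,
    TrainConfig,
    forward_batch,
    predict_image,
    train,
    train_kfold,
)
from .synth import MScanCube, PhantomLayout, SimulationConfig, simulate_phantom_mscan

__all__ = [
    "ExperimentConfig",
    "SAMPLE_TYPES",
    "default_experiment_config",
    "cycle_group_slice",
    "run_phantom_pipeline",
    "run_cycle_group_study",
    "run_cross_sample_study",
    "run_input_length_study",
    "run_experiment",
]

_MAX_SEED = 2**31

#: Parameter distributions defining the three synthetic sample types of the
#: cross-sample study: a dye phantom, a lipid-rich plaque analogue and an
#: adipose-tissue analogue.  The types differ chiefly in signal *shape* —
#: thermal time constant and bulk-heating-to-modulation ratio — at matched
#: noise level and comparable amplitude range, so cross-type transfer
#: penalties reflect distributional shift rather than unequal difficulty.
SAMPLE_TYPES: dict[str, dict] = {
    "phantom": {"powers_mw": (0.0, 1.0, 2.25, 3.5), "overrides": {}},
    "lipid": {
        "powers_mw": (0.0, 1.6, 3.2),
        "overrides": {
            "transient_tau_s": 0.006,
            "plateau_rad_per_mw": 0.06,
            "pink_noise_scale_rad": 0.012,
        },
    },
    "adipose": {
        "powers_mw": (0.0, 1.25, 2.5),
        "overrides": {
            "transient_tau_s": 0.0025,
            "plateau_rad_per_mw": 0.015,
            "responsivity_rad_per_mw": 0.04,
            "pink_noise_scale_rad": 0.012,
        },
    },
}


@dataclass
class ExperimentConfig:
    """Bundle of all knobs for one study run."""

    experiment: str = "phantom"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    layout: PhantomLayout | None = None
    net: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    cycles_grid: tuple[float, ...] = (1, 1.5, 2, 3, 4)
    sample_types: tuple[str, ...] = ("phantom", "lipid", "adipose")
    n_groups: int = 9
    samples_per_cycle: int = 44
    cycles_per_group: int = 2
    train_fraction: float = 0.7
    out_of_focus_shift_px: int = 50
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.experiment not in (
            "phantom",
            "cycle_group",
            "cross_sample",
            "input_length",
        ):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if not self.cycles_grid or not self.sample_types:
            raise ValueError("sweep lists must be non-empty")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        max_len = max(round(c * self.samples_per_cycle) for c in self.cycles_grid)
        if max_len > self.simulation.n_samples:
            raise ValueError("sweep lengths exceed n_samples")


def default_experiment_config(experiment: str = "phantom") -> ExperimentConfig:
    """Desk-scale defaults for each study (pools and epochs reduced from the
    full-scale 80 000-pair / 120-epoch recipe so a study runs in minutes)."""
    if experiment == "phantom":
        return ExperimentConfig(
            experiment="phantom",
            layout=PhantomLayout.bands(n_depth=110, n_lateral=160),
            train=TrainConfig(pool_size=20000, epochs=40, batch_size=512, k_folds=10),
        )
    if experiment == "cycle_group":
        return ExperimentConfig(
            experiment="cycle_group",
            layout=PhantomLayout.bands(n_depth=110, n_lateral=60),
            train=TrainConfig(pool_size=5000, epochs=25, batch_size=256, restarts=2),
        )
    if experiment == "cross_sample":
        return ExperimentConfig(
            experiment="cross_sample",
            train=TrainConfig(pool_size=6000, epochs=25, batch_size=256, restarts=2),
        )
    if experiment == "input_length":
        return ExperimentConfig(
            experiment="input_length",
            layout=PhantomLayout.bands(n_depth=110, n_lateral=80),
            train=TrainConfig(pool_size=8000, epochs=30, batch_size=256, restarts=2),
            cycles_grid=(1, 1.5, 2, 3, 4),
        )
    raise ValueError(f"unknown experiment {experiment!r}")


def cycle_group_slice(
    group_index: int, samples_per_cycle: int = 44, cycles_per_group: int = 2
) -> tuple[int, int]:
    """Half-open sample range of cycle group ``group_index`` (1-based).

    Group 1 covers the first two modulation cycles, group 2 cycles 3-4, etc.
    """
    if samples_per_cycle < 1 or cycles_per_group < 1:
        raise ValueError("samples_per_cycle and cycles_per_group must be positive")
    if not 1 <= group_index <= 9:
        raise ValueError("group_index must be in 1..9")
    width = cycles_per_group * samples_per_cycle
    start = (group_index - 1) * width
    return start, start + width


def _provenance(config: ExperimentConfig, seed: int) -> dict:
    from . import __version__

    parts = [config.simulation, config.net, config.train]
    if config.layout is not None:
        parts.append(config.layout)
    return {
        "experiment": config.experiment,
        "config_hash": _io.config_hash(*parts),
        "seed": seed,
        "version": __version__,
    }


def _band_column_split(
    layout: PhantomLayout, train_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split lateral columns 70/30 within every power band, so both the
    training and held-out regions contain all power levels."""
    band_of_col = layout.region_labels[layout.surface_row]
    train_cols, test_cols = [], []
    for band in np.unique(band_of_col):
        cols = np.nonzero(band_of_col == band)[0]
        cut = int(round(cols.size * train_fraction))
        train_cols.append(cols[:cut])
        test_cols.append(cols[cut:])
    return np.concatenate(train_cols), np.concatenate(test_cols)


def _subcube(cube: MScanCube, cols: np.ndarray) -> MScanCube:
    return MScanCube(
        phase_rad=cube.phase_rad[:, cols, :],
        oct_intensity_db=cube.oct_intensity_db[:, cols],
        config=cube.config,
        layout=None,
    )


@dataclass
class PhantomPipelineResult:
    """Held-out images and metrics for the in- and out-of-focus conditions."""

    images: dict[str, dict[str, object]]  # condition -> {"GT","ST","NET"}
    reports: dict[str, MetricsReport]
    mse_st_gt: dict[str, float]
    mse_net_gt: dict[str, float]
    folds: list[FoldResult]
    selected: FoldResult
    net_val_mse: float
    st_val_mse: float
    params: NetworkParams
    provenance: dict

    def report_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "net_val_mse": self.net_val_mse,
            "st_val_mse": self.st_val_mse,
            "fold_val_mse": [f.val_mse for f in self.folds],
            "mse_st_gt": self.mse_st_gt,
            "mse_net_gt": self.mse_net_gt,
            "reports": {
                k: json.loads(r.to_json()) for k, r in self.reports.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def run_phantom_pipeline(
    config: ExperimentConfig | None = None, seed: int = 0
) -> PhantomPipelineResult:
    """Train on lateral training regions of an in- and out-of-focus cube,
    evaluate GT / ST / NET on the held-out lateral region of each."""
    config = config or default_experiment_config("phantom")
    layout = config.layout or PhantomLayout.bands()
    rng = np.random.default_rng(seed)
    sim_in = config.simulation
    sim_out = sim_in.replace(
        focal_depth_px=sim_in.focal_depth_px + config.out_of_focus_shift_px
    )
    cube_in, _ = simulate_phantom_mscan(layout, sim_in, seed=int(rng.integers(_MAX_SEED)))
    cube_out, _ = simulate_phantom_mscan(
        layout, sim_out, seed=int(rng.integers(_MAX_SEED))
    )
    train_cols, test_cols = _band_column_split(layout, config.train_fraction)

    pairs = [
        extract_training_pairs(c, lateral_slice=train_cols) for c in (cube_in, cube_out)
    ]
    X = np.concatenate([p.inputs for p in pairs])
    y = np.concatenate([p.labels for p in pairs])
    tc = dataclasses.replace(config.train, seed=int(rng.integers(_MAX_SEED)))
    folds, selected = train_kfold((X, y), config.net, tc)

    # conventional short-trace estimate on the selected fold's validation pairs
    n_short = config.net.layer_sizes[0]
    X_val, y_val = X[selected.val_indices], y[selected.val_indices]
    st_val = lockin_amplitude_array(
        X_val, sim_in.a_line_rate_hz, sim_in.mod_freq_hz, n_short
    )
    st_val_mse = float(np.mean((st_val - y_val) ** 2))

    images: dict[str, dict[str, object]] = {}
    reports: dict[str, MetricsReport] = {}
    mse_st, mse_net = {}, {}
    from .metrics import mse_images  # local import to avoid cycle at module load

    for name, cube in (("on_focus", cube_in), ("off_focus", cube_out)):
        sub = _subcube(cube, test_cols)
        gt = reconstruct_image(sub, n_use=864)
        st = reconstruct_image(sub, n_use=n_short)
        net = predict_image(selected.params, sub, n_short=n_short)
        regions = regions_from_labels(layout.region_labels[:, test_cols])
        reports[name] = metrics_report(gt, st, net, regions)
        images[name] = {"GT": gt, "ST": st, "NET": net}
        mse_st[name] = mse_images(gt, st)
        mse_net[name] = mse_images(gt, net)

    result = PhantomPipelineResult(
        images=images,
        reports=reports,
        mse_st_gt=mse_st,
        mse_net_gt=mse_net,
        folds=folds,
        selected=selected,
        net_val_mse=selected.val_mse,
        st_val_mse=st_val_mse,
        params=selected.params,
        provenance=_provenance(config, seed),
    )
    if config.output_dir:
        _write_phantom_artifacts(result, config, seed)
    return result


def _write_phantom_artifacts(
    result: PhantomPipelineResult, config: ExperimentConfig, seed: int
) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cond, imgs in result.images.items():
        for kind, img in imgs.items():
            _io.save_image(out / f"{cond}_{kind.lower()}_seed{seed}.tiff", img)
    _io.save_model(out / f"model_seed{seed}.json", result.params, config.net, seed)
    (out / f"phantom_report_seed{seed}.json").write_text(result.report_json())


def _group_dataset(
    cube: MScanCube,
    gt_labels: np.ndarray,
    pix_rows: np.ndarray,
    pix_cols: np.ndarray,
    group: int,
    config: ExperimentConfig,
) -> tuple[np.ndarray, np.ndarray]:
    start, end = cycle_group_slice(
        group, config.samples_per_cycle, config.cycles_per_group
    )
    X = reference_trace(cube.phase_rad[pix_rows, pix_cols, start:end])
    return X, gt_labels


def run_cycle_group_study(
    config: ExperimentConfig | None = None, seed: int = 0
) -> np.ndarray:
    """Train one net per two-cycle group, cross-test on all groups.

    Entry ``(g, h)`` of the returned 9 x 9 matrix is the MSE (against the
    full-record lock-in GT) of the network trained on group ``g + 1`` when
    fed held-out inputs from group ``h + 1``.
    """
    config = config or default_experiment_config("cycle_group")
    layout = config.layout or PhantomLayout.bands(n_depth=110, n_lateral=60)
    width = config.cycles_per_group * config.samples_per_cycle
    gt_n_use = config.n_groups * width
    if config.simulation.n_samples < gt_n_use:
        raise ValueError(
            f"need n_samples >= {gt_n_use} for {config.n_groups} groups"
        )
    rng = np.random.default_rng(seed)
    cube, _ = simulate_phantom_mscan(
        layout, config.simulation, seed=int(rng.integers(_MAX_SEED))
    )
    mask = intensity_mask(cube.oct_intensity_db, config.simulation.oct_noise_floor_db)
    rows, cols = np.nonzero(mask)
    order = rng.permutation(rows.size)
    n_train = int(round(rows.size * config.train_fraction))
    tr, te = order[:n_train], order[n_train:]

    gt_all = lockin_amplitude_array(
        reference_trace(cube.phase_rad[rows, cols, :]),
        config.simulation.a_line_rate_hz,
        config.simulation.mod_freq_hz,
        gt_n_use,
    )

    net_cfg = dataclasses.replace(config.net, layer_sizes=(width,) + tuple(
        config.net.layer_sizes[1:]
    ))
    mse = np.empty((config.n_groups, config.n_groups))
    test_inputs = []
    for h in range(1, config.n_groups + 1):
        start, end = cycle_group_slice(
            h, config.samples_per_cycle, config.cycles_per_group
        )
        test_inputs.append(
            reference_trace(cube.phase_rad[rows[te], cols[te], start:end])
        )
    for g in range(1, config.n_groups + 1):
        start, end = cycle_group_slice(
            g, config.samples_per_cycle, config.cycles_per_group
        )
        Xg = reference_trace(cube.phase_rad[rows[tr], cols[tr], start:end])
        params, _ = train(
            Xg, gt_all[tr], net_cfg, config.train, seed=int(rng.integers(_MAX_SEED))
        )
        for h in range(config.n_groups):
            pred = forward_batch(params, test_inputs[h])
            mse[g - 1, h] = float(np.mean((pred - gt_all[te]) ** 2))
    return mse


def _sample_type_cube(
    name: str, base: SimulationConfig, seed: int, n_lateral: int = 60
) -> MScanCube:
    spec = SAMPLE_TYPES[name]
    sim = base.replace(**spec["overrides"])
    layout = PhantomLayout.bands(
        powers_mw=spec["powers_mw"], n_depth=110, n_lateral=n_lateral
    )
    cube, _ = simulate_phantom_mscan(layout, sim, seed=seed)
    return cube


def run_cross_sample_study(
    config: ExperimentConfig | None = None, seed: int = 0
) -> np.ndarray:
    """Per-type and pooled networks cross-tested over three sample types.

    Rows: networks trained on each sample type in ``config.sample_types``
    order, then the pooled network; columns: held-out test data per type.
    """
    config = config or default_experiment_config("cross_sample")
    rng = np.random.default_rng(seed)
    n_short = config.net.layer_sizes[0]
    train_sets, test_sets = [], []
    for name in config.sample_types:
        cube = _sample_type_cube(
            name, config.simulation, seed=int(rng.integers(_MAX_SEED))
        )
        cols_tr, cols_te = _band_column_split(cube.layout, config.train_fraction)
        p_tr = extract_training_pairs(cube, n_short=n_short, lateral_slice=cols_tr)
        p_te = extract_training_pairs(cube, n_short=n_short, lateral_slice=cols_te)
        train_sets.append((p_tr.inputs, p_tr.labels))
        test_sets.append((p_te.inputs, p_te.labels))

    nets = []
    for X, y in train_sets:
        params, _ = train(
            X, y, config.net, config.train, seed=int(rng.integers(_MAX_SEED))
        )
        nets.append(params)
    X_pool = np.concatenate([X for X, _ in train_sets])
    y_pool = np.concatenate([y for _, y in train_sets])
    pooled, _ = train(
        X_pool, y_pool, config.net, config.train, seed=int(rng.integers(_MAX_SEED))
    )
    nets.append(pooled)

    mse = np.empty((len(nets), len(test_sets)))
    for i, params in enumerate(nets):
        for j, (Xt, yt) in enumerate(test_sets):
            mse[i, j] = float(np.mean((forward_batch(params, Xt) - yt) ** 2))
    return mse


def run_input_length_study(
    config: ExperimentConfig | None = None, seed: int = 0
) -> list[dict[str, float]]:
    """Sweep input length (in modulation cycles) with a [n, 40, 20, 5, 1] net.

    For each grid point, trains on inputs of ``round(cycles * 44)`` samples
    and reports the network's held-out MSE against the 20-cycle GT alongside
    the conventional short-trace reconstruction of the same length.  Returns
    one ``{"cycles", "n_input", "net_mse", "st_mse"}`` row per grid point.
    """
    config = config or default_experiment_config("input_length")
    layout = config.layout or PhantomLayout.bands(n_depth=110, n_lateral=80)
    sim = config.simulation
    # GT convention for this study: first 20 nominal cycles of 44 samples
    gt_n_use = 20 * config.samples_per_cycle
    if sim.n_samples < gt_n_use:
        raise ValueError("need n_samples >= 880 (20 cycles of 44 samples)")
    rng = np.random.default_rng(seed)
    cube, _ = simulate_phantom_mscan(layout, sim, seed=int(rng.integers(_MAX_SEED)))
    mask = intensity_mask(cube.oct_intensity_db, sim.oct_noise_floor_db)
    rows, cols = np.nonzero(mask)
    order = rng.permutation(rows.size)
    n_train = int(round(rows.size * config.train_fraction))
    tr, te = order[:n_train], order[n_train:]
    traces = reference_trace(cube.phase_rad[rows, cols, :])
    gt = lockin_amplitude_array(traces, sim.a_line_rate_hz, sim.mod_freq_hz, gt_n_use)

    table = []
    for cycles in config.cycles_grid:
        n_in = int(round(cycles * config.samples_per_cycle))
        net_cfg = NetworkConfig(layer_sizes=(n_in, 40, 20, 5, 1))
        params, _ = train(
            traces[tr, :n_in],
            gt[tr],
            net_cfg,
            config.train,
            seed=int(rng.integers(_MAX_SEED)),
        )
        pred = forward_batch(params, traces[te, :n_in])
        st = lockin_amplitude_array(
            traces[te], sim.a_line_rate_hz, sim.mod_freq_hz, n_in
        )
        table.append(
            {
                "cycles": float(cycles),
                "n_input": n_in,
                "net_mse": float(np.mean((pred - gt[te]) ** 2)),
                "st_mse": float(np.mean((st - gt[te]) ** 2)),
            }
        )
    return table


def run_experiment(config: ExperimentConfig, seed: int = 0):
    """Dispatch to the study named by ``config.experiment``."""
    runner = {
        "phantom": run_phantom_pipeline,
        "cycle_group": run_cycle_group_study,
        "cross_sample": run_cross_sample_study,
        "input_length": run_input_length_study,
    }[config.experiment]
    return runner(config, seed=seed)
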