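"""Seeded end-to-end benchmark runs over a phantom x noise grid.

Each grid cell (noise kind, level, replicate) generates ONE noisy image
from a per-cell seed, and every configured method — each ensemble member,
the plain KL consensus and the spatial KL consensus — is run on that same
image, so methods are compared under identical corruption. Results come
back as a long-format table (one row per method per cell) that is fully
reproducible from the configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import KLConsensus, concatenate_normalize
from .fcm import DEFAULT_MEMBERS, FuzzyCMeans, SpatialFuzzyCMeans, _parse_member
from .metrics import align_labels, defuzzify, segmentation_accuracy
from .phantoms import NoiseSpec, add_noise, make_trin_phantom, make_two_value_phantom

log = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_experiment", "summarize_experiment",
           "run_methods_on_image", "read_experiment_config", "member_label"]

_PHANTOMS = {"two_value": make_two_value_phantom, "trin": make_trin_phantom}


@dataclass
class ExperimentConfig:
    """Grid definition for a benchmark run.

    ``levels`` are noise percentages; ``members`` are ensemble member specs
    (see :func:`fcekl.fcm.generate_basic_partitions`). All cell seeds derive
    from ``seed`` so re-running the config reproduces the table exactly.
    """

    phantom: str = "two_value"
    size: int | None = None
    noise_kinds: tuple = ("gaussian", "rician")
    levels: tuple = (5.0, 10.0, 20.0, 50.0)
    replicates: int = 5
    seed: int = 0
    n_clusters: int | None = None
    members: tuple = DEFAULT_MEMBERS
    window: int = 5
    m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 100

    def __post_init__(self):
        if self.phantom not in _PHANTOMS:
            raise ValueError(f"unknown phantom {self.phantom!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def make_phantom(self):
        fn = _PHANTOMS[self.phantom]
        return fn(self.size) if self.size else fn()


def member_label(index: int, spec) -> str:
    """Stable human-readable column name for an ensemble member."""
    name, kwargs = _parse_member(spec)
    if name == "sfcm":
        return f"sfcm_w{kwargs.get('window', 3)}"
    return f"{name}_{chr(ord('a') + index)}"


def _cell_seed(base: int, *coords: int) -> int:
    return int(np.random.SeedSequence([int(base), *map(int, coords)]).generate_state(1)[0] % (2**31))


def run_methods_on_image(image: np.ndarray, truth: np.ndarray, cfg: ExperimentConfig,
                         seed: int) -> dict:
    """Run all ensemble members and both consensus variants on one image.

    Returns {method name: aligned segmentation accuracy}.
    """
    c = cfg.n_clusters or int(truth.max()) + 1
    members = list(cfg.members)
    child = np.random.SeedSequence(seed).generate_state(len(members) + 1)
    partitions, sas = [], {}
    for i, spec in enumerate(members):
        name, kwargs = _parse_member(spec)
        kwargs = dict(kwargs)
        c_f = int(kwargs.pop("c", c))
        cls = {"fcm": FuzzyCMeans, "sfcm": SpatialFuzzyCMeans}[name]
        model = cls(image, c_f, m=cfg.m, tol=cfg.tol, max_iter=cfg.max_iter, **kwargs)
        res = model.fit(seed=int(child[i]))
        partitions.append(res.memberships)
        pred = align_labels(defuzzify(res.memberships, truth.shape), truth)
        sas[member_label(i, spec)] = segmentation_accuracy(pred, truth)
    profiles = concatenate_normalize(partitions)
    for spatial, label in ((False, "fce_kl"), (True, "fce_skl")):
        model = KLConsensus(profiles, c, m=cfg.m, spatial=spatial, grid_shape=truth.shape,
                            window=cfg.window, tol=cfg.tol, max_iter=cfg.max_iter)
        res = model.fit(seed=int(child[-1]))
        pred = align_labels(res.labels(truth.shape), truth)
        sas[label] = segmentation_accuracy(pred, truth)
    return sas


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Run the full grid; returns a long table with one row per method/cell.

    A failing cell is logged with its coordinates and marked failed
    (sa = NaN); the run continues.
    """
    phantom = cfg.make_phantom()
    rows = []
    for ik, kind in enumerate(cfg.noise_kinds):
        for il, level in enumerate(cfg.levels):
            for rep in range(cfg.replicates):
                cell = _cell_seed(cfg.seed, ik, int(round(level * 100)), rep)
                try:
                    noisy = add_noise(phantom, NoiseSpec(kind=kind, level_percent=level, seed=cell))
                    sas = run_methods_on_image(noisy, phantom.labels, cfg, seed=cell)
                    status = "ok"
                except Exception as exc:  # keep the grid going
                    log.error("cell (%s, %s%%, rep %d) failed: %s", kind, level, rep, exc)
                    sas, status = {"error": np.nan}, "failed"
                for method, sa in sas.items():
                    rows.append({
                        "phantom": cfg.phantom, "noise": kind, "level": level,
                        "replicate": rep, "seed": cell, "method": method,
                        "sa": sa, "status": status,
                    })
    return pd.DataFrame(rows)


def summarize_experiment(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean and standard deviation of accuracy across replicates."""
    g = table[table.status == "ok"].groupby(["phantom", "noise", "level", "method"])["sa"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"mean": "sa_mean", "std": "sa_sd", "count": "n_replicates"})


def read_experiment_config(path) -> ExperimentConfig:
    """Parse a flat ``key = value`` text file into an ExperimentConfig.

    Recognized keys: phantom, size, noise_kinds, levels, replicates, seed,
    clusters, members, window, m, tol, max_iter. Lists are comma-separated;
    lines starting with '#' are ignored.
    """
    kv = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise IOError(f"{path}: malformed config line {line!r} (expected key = value)")
            key, val = (s.strip() for s in line.split("=", 1))
            kv[key] = val
    kwargs = {}
    if "phantom" in kv:
        kwargs["phantom"] = kv["phantom"]
    if "size" in kv:
        kwargs["size"] = int(kv["size"])
    if "noise_kinds" in kv:
        kwargs["noise_kinds"] = tuple(s.strip() for s in kv["noise_kinds"].split(","))
    if "levels" in kv:
        kwargs["levels"] = tuple(float(s) for s in kv["levels"].split(","))
    if "replicates" in kv:
        kwargs["replicates"] = int(kv["replicates"])
    if "seed" in kv:
        kwargs["seed"] = int(kv["seed"])
    if "clusters" in kv:
        kwargs["n_clusters"] = int(kv["clusters"])
    if "members" in kv:
        kwargs["members"] = tuple(s.strip() for s in kv["members"].split(","))
    if "window" in kv:
        kwargs["window"] = int(kv["window"])
    if "m" in kv:
        kwargs["m"] = float(kv["m"])
    if "tol" in kv:
        kwargs["tol"] = float(kv["tol"])
    if "max_iter" in kv:
        kwargs["max_iter"] = int(kv["max_iter"])
    return ExperimentConfig(**kwargs)
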