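"""End-to-end orchestration on synthetic data.

Stages: generate synthetic owl heads -> build cue maps (reliability,
gain, interaural correlation) -> simulate an ICx population weighted by
the reliability map -> extract tuning features -> match tuning against
the cue-map predictors.  Every stage is seeded from the config and the
run writes tidy CSV/JSON outputs plus a manifest with content hashes,
per-stage runtimes and the config itself.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binaural import design_owl_gammatone_bank
from .cues import band_edges, build_cue_maps, build_gain_map
from .hrtf import HeadModelParams, generate_hrir_set, save_hrir_set
from .matching import match_population
from .neurons import simulate_population
from .tuning import best_itd, frequency_tuning_features, mean_rate_curve

__all__ = ["RunConfig", "run_full_study", "analyze_population"]


def _grid(spec: dict) -> np.ndarray:
    return np.arange(spec["start"], spec["stop"] + 1e-9, spec["step"])


@dataclass
class RunConfig:
    """Validated configuration of a full synthetic study."""

    out_dir: str
    n_owls: int = 10
    head: dict = field(default_factory=dict)          # HeadModelParams overrides
    bank: dict = field(default_factory=dict)          # design_owl_gammatone_bank kwargs
    target_grid: dict = field(default_factory=lambda: {"start": -90, "stop": 90, "step": 5})
    distractor_grid: dict = field(default_factory=lambda: {"start": -90, "stop": 90, "step": 5})
    n_neurons: int = 100
    trials: int = 20
    seed_heads: int = 1000
    seed_maps: int = 2000
    seed_neurons: int = 3000
    save_hrirs: bool = False

    def __post_init__(self) -> None:
        if self.n_owls < 1:
            raise ValueError("n_owls must be >= 1")
        if self.n_neurons < 10:
            raise ValueError("n_neurons must be >= 10")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        for name in ("target_grid", "distractor_grid"):
            g = getattr(self, name)
            if not {"start", "stop", "step"} <= set(g):
                raise ValueError(f"{name} needs start/stop/step")
            if g["step"] <= 0 or g["stop"] <= g["start"]:
                raise ValueError(f"{name} is not a valid ascending grid")
        for name in ("seed_heads", "seed_maps", "seed_neurons"):
            if not isinstance(getattr(self, name), int):
                raise ValueError(f"{name} must be an explicit integer seed")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f)
        return cls(**data)

    def head_params(self) -> HeadModelParams:
        return HeadModelParams(**self.head)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def analyze_population(population, channel_fcs_hz) -> pd.DataFrame:
    """Tuning features for each simulated neuron.

    Returns one row per neuron: recovered BF and frequency edges from
    the tone-frequency curve, recovered best ITD from the broadband ITD
    curve, the (spontaneous-subtracted) tuning rates, and the ground
    truth carried in the simulation parameters.
    """
    rows = []
    for p, curves in population:
        f, rates = mean_rate_curve(curves["tone_frequency"])
        feats = frequency_tuning_features(f, rates)
        itd_grid, itd_rates = mean_rate_curve(curves["broadband_itd"])
        bi = best_itd(itd_grid, itd_rates)
        rows.append(
            {
                "bf_hz": feats["bf_hz"],
                "f_low_hz": feats["f_low_hz"],
                "f_high_hz": feats["f_high_hz"],
                "best_itd_us": bi["best_itd_us"],
                "abs_best_itd_us": bi["abs_best_itd_us"],
                "true_best_itd_us": p.best_itd_us,
                "map_location_index": p.meta.get("map_location_index", -1),
                "tuning_rates": rates,
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_study(config: RunConfig) -> dict:
    """Run every stage; returns the result bundle and writes outputs.

    Deterministic given the config seeds: running the same config twice
    produces byte-identical output files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runtimes: dict[str, float] = {}
    bundle: dict = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                runtimes[name] = round(time.perf_counter() - self.t, 3)
                if exc_type is not None:
                    raise RuntimeError(f"pipeline stage '{name}' failed") from exc

        return _Timer()

    base = config.head_params()
    bank = design_owl_gammatone_bank(**config.bank)
    target_grid = _grid(config.target_grid)
    distractor_grid = _grid(config.distractor_grid)

    with stage("generate_heads"):
        heads = [
            generate_hrir_set(base, seed=config.seed_heads + i)
            for i in range(config.n_owls)
        ]
        if config.save_hrirs:
            for i, h in enumerate(heads):
                save_hrir_set(h, out / f"owl_{i:02d}.h5")

    with stage("cue_maps"):
        rmaps, imaps = [], []
        for i, h in enumerate(heads):
            rmap, imap = build_cue_maps(
                h, bank, target_grid, distractor_grid, seed=config.seed_maps + i
            )
            rmaps.append(rmap)
            imaps.append(imap)
        rmap0, imap0 = rmaps[0], imaps[0]
        gmap0 = build_gain_map(heads[0], bank.center_freqs_hz, target_grid)
        bundle.update(reliability_maps=rmaps, iac_maps=imaps, gain_map=gmap0)
        pd.concat([m.to_tidy() for m in (rmap0, imap0, gmap0)]).to_csv(
            out / "cue_maps_owl00.csv", index=False
        )
        if config.n_owls > 1:
            cross_owl_sd = np.std([m.reliability_norm for m in rmaps], axis=0, ddof=0)
            bundle["cross_owl_reliability_sd"] = cross_owl_sd
            pd.DataFrame(
                cross_owl_sd,
                index=pd.Index(target_grid, name="target_azimuth"),
                columns=bank.center_freqs_hz,
            ).to_csv(out / "cross_owl_reliability_sd.csv")

    with stage("simulate_population"):
        population = simulate_population(
            rmap0,
            base,
            n_neurons=config.n_neurons,
            trials=config.trials,
            seed=config.seed_neurons,
        )
        bundle["population"] = population

    with stage("analyze_tuning"):
        features = analyze_population(population, bank.center_freqs_hz)
        bundle["features"] = features
        features.drop(columns=["tuning_rates"]).to_csv(
            out / "population_features.csv", index=False
        )

    with stage("match"):
        loc = features["map_location_index"].to_numpy()
        predictors = {
            "reliability": rmap0.reliability_norm[loc],
            "gain": gmap0.gain_norm_per_location[loc],
            "gain_freq_then_location": gmap0.gain_norm_freq_then_location[loc],
        }
        map_edges = np.array(
            [band_edges(rmap0.channel_fcs_hz, rmap0.reliability_norm[i]) for i in loc]
        )
        match = match_population(features, predictors, map_edges)
        bundle["match"] = match
        match.to_json(out / "match_result.json")
        match.per_neuron.to_csv(out / "match_per_neuron.csv", index=False)

    outputs = sorted(
        p for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "runtimes_s": runtimes,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    bundle["manifest"] = manifest
    return bundle
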