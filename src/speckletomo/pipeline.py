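"""Run configuration, manifest and the end-to-end pipeline.

A run is fully described by a JSON config; ``end_to_end`` executes
phantom -> two independent MC trajectory sets -> ground-truth speckle
images (optionally noise-perturbed) -> reconstruction from the second set
-> error report, and writes a manifest (config hash, per-stage seeds, file
checksums, package version) sufficient to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

from . import __version__
from .experiments import ScaledStudy, run_scaled_study
from .forward import ForwardConfig, save_speckle_image
from .phantom import save_geometry
from .reconstruct import ReconConfig
from .transport import save_trajectories

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "end_to_end", "RunManifest"]


@dataclass(frozen=True)
class RunConfig:
    """Validated top-level configuration with all defaults filled."""

    study: ScaledStudy = field(default_factory=ScaledStudy)
    forward: ForwardConfig = field(default_factory=ForwardConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    noise_levels: tuple[float, ...] = ()
    n_noise_seeds: int = 3
    seed: int = 1
    output_dir: str = "speckletomo_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


_SECTION_TYPES = {"study": ScaledStudy, "forward": ForwardConfig, "recon": ReconConfig}


def _build_section(cls, data: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in '{name}': {sorted(unknown)}")
    # JSON lists -> tuples where the dataclass default is a tuple
    coerced = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        coerced[k] = v
    return cls(**coerced)


def load_config(path_or_dict) -> RunConfig:
    """Load and validate a run config; unknown keys are rejected by name."""
    if isinstance(path_or_dict, (str, os.PathLike)):
        with open(path_or_dict) as fh:
            data = json.load(fh)
    else:
        data = dict(path_or_dict)
    top_allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - top_allowed
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            kwargs[name] = _build_section(cls, data[name], name)
    for scalar in ("n_noise_seeds", "seed", "output_dir"):
        if scalar in data:
            kwargs[scalar] = data[scalar]
    if "noise_levels" in data:
        kwargs["noise_levels"] = tuple(data["noise_levels"])
    return RunConfig(**kwargs)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    """Inventory of a completed run."""

    config_hash: str
    seed: int
    version: str
    files: dict[str, str]  # path -> sha256

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def end_to_end(cfg: RunConfig) -> RunManifest:
    """Execute the full pipeline described by ``cfg`` and write all outputs."""
    out = cfg.output_dir
    os.makedirs(out, exist_ok=True)
    stage = "study"
    try:
        result = run_scaled_study(
            cfg.seed,
            study=cfg.study,
            fwd=cfg.forward,
            recon_cfg=cfg.recon,
            noise_levels=cfg.noise_levels,
            n_noise_seeds=cfg.n_noise_seeds,
        )
        stage = "outputs"
        save_geometry(os.path.join(out, "phantom"), result["geometry"], result["strands"])
        for b in result["sources_recon"]:
            save_trajectories(
                os.path.join(out, f"traj_recon_src{b.source.source_id}.h5"), b
            )
        for img in result["truth_images"]:
            save_speckle_image(os.path.join(out, f"speckle_src{img.source_id}"), img)
        truth = result["truth"]
        flows = result["flows"]
        import pandas as pd

        pd.DataFrame(
            {"group_id": truth.group_ids, "v_mm_s": truth.v}
        ).to_csv(os.path.join(out, "flows_true.csv"), index=False)
        pd.DataFrame(
            {"group_id": flows.group_ids, "v_mm_s": flows.v}
        ).to_csv(os.path.join(out, "flows_hat.csv"), index=False)
        result["errors"].to_csv(os.path.join(out, "errors.csv"))
        result["trace"].to_csv(os.path.join(out, "trace.csv"), index=False)
        if result["noise"]:
            pd.DataFrame(result["noise"]).to_csv(
                os.path.join(out, "noise_summary.csv"), index=False
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    files = {}
    for root, _, names in os.walk(out):
        for n in sorted(names):
            p = os.path.join(root, n)
            files[os.path.relpath(p, out)] = _sha256(p)
    manifest = RunManifest(
        config_hash=config_hash(cfg), seed=cfg.seed, version=__version__, files=files
    )
    manifest.save(os.path.join(out, "manifest.json"))
    logger.info("run complete: %d files in %s", len(files), out)
    return manifest
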