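"""End-to-end pipeline drivers: configuration, orchestration, manifests.

``run_2d_pipeline`` reproduces the TIRF analysis flow: segment cells from
the reference channel, rolling-ball background subtraction, per-cell MFI and
PCC, radial averaging and profiles, and group aggregation.
``run_3d_pipeline`` reproduces the confocal flow: membrane mask, internal
antigen-positive vesicles, released receptor-positive vesicles, per-object
and per-cell tables.  Every run writes a JSON manifest recording inputs,
parameters, seed and software version, so outputs are reproducible and two
runs with identical config and seed produce byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coloc import CellQuantRecord, aggregate, mfi, pcc
from .images import MultiChannelImage, VolumeStack
from .radial import cohort_radial_average, radial_average_image, radial_profile
from .segmentation2d import segment_cells, subtract_background
from .synthetic import StackSpec, SynapseSpec, render_stack, render_synapse
from .vesicle3d import build_cell_mask, per_cell_summary, segment_vesicles
from .images import write_json

logger = logging.getLogger("synquant")

__all__ = ["PipelineConfig", "run_2d_pipeline", "run_3d_pipeline"]


@dataclass
class PipelineConfig:
    """All parameters of a 2D or 3D analysis run.

    ``channels`` maps roles (reference, adhesion, receptor, adaptor,
    membrane, cargo) to channel names in the input images.  ``inputs`` lists
    TIFF paths; when empty, ``n_demo`` synthetic fixtures are generated with
    seeds derived from ``seed``.
    """

    output_dir: str = "synquant_out"
    seed: int = 0
    inputs: list[str] = field(default_factory=list)
    n_demo: int = 3
    channels: dict[str, str] = field(
        default_factory=lambda: {
            "reference": "brightfield",
            "adhesion": "adhesion",
            "receptor": "receptor",
            "adaptor": "adaptor",
            "membrane": "membrane",
            "cargo": "antigen",
            "released_cargo": "receptor",
        }
    )
    pixel_size_um: float = 0.1
    ball_radius_px: int = 50
    min_area_um2: float = 20.0
    bin_width_um: float = 0.25
    pcc_pairs: list[list[str]] = field(default_factory=lambda: [["receptor", "adaptor"]])
    radial_method: str = "polar"
    smoothing_um: float = 0.3
    min_voxels: int = 4

    def validate(self) -> None:
        if self.pixel_size_um <= 0 or self.bin_width_um <= 0 or self.min_area_um2 <= 0:
            raise ValueError("sizes must be positive")
        if self.ball_radius_px < 1 or self.min_voxels < 1:
            raise ValueError("ball radius and min_voxels must be >= 1")
        if self.n_demo < 1 and not self.inputs:
            raise ValueError("need input images or n_demo >= 1")
        roles_2d = {"reference"} | {r for pair in self.pcc_pairs for r in pair}
        for role in roles_2d:
            if role not in self.channels:
                raise ValueError(f"channel role {role!r} missing from config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _derived_seed(seed: int, index: int) -> int:
    return int((seed * 100_003 + index) % (2**31))


def _load_or_generate_2d(config: PipelineConfig) -> list[tuple[str, MultiChannelImage]]:
    if config.inputs:
        return [(p, MultiChannelImage.from_tiff(p)) for p in config.inputs]
    images = []
    for i in range(config.n_demo):
        spec = SynapseSpec(seed=_derived_seed(config.seed, i), pixel_size_um=config.pixel_size_um)
        img, _ = render_synapse(spec)
        images.append((f"demo_2d_{i}", img))
    return images


def _check_channels(img, roles: list[str], config: PipelineConfig, name: str) -> None:
    for role in roles:
        ch = config.channels.get(role)
        if ch is None or ch not in img:
            raise ValueError(f"{name}: channel {ch!r} for role {role!r} not found")


def run_2d_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the 2D TIRF analysis; returns the paths of the written artifacts."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    images = _load_or_generate_2d(config)
    roles = ["reference"] + sorted({r for pair in config.pcc_pairs for r in pair})
    for name, img in images:
        _check_channels(img, roles, config, name)

    records = []
    profiles = []
    profile_rows = []
    for exp_idx, (name, img) in enumerate(images):
        ref = img[config.channels["reference"]]
        cells = segment_cells(ref, config.min_area_um2, img.pixel_size_um)
        logger.info("image %s: %d cells", name, len(cells))
        corrected = {
            role: subtract_background(img[config.channels[role]], config.ball_radius_px)
            for role in roles
            if role != "reference"
        }
        for cell in cells:
            rec = CellQuantRecord(
                cell_id=cell.label_id,
                experiment=name,
                mfi={role: mfi(corrected[role], cell.mask) for role in corrected},
                pcc={
                    (a, b): pcc(corrected[a], corrected[b], cell.mask)
                    for a, b in config.pcc_pairs
                },
            )
            records.append(rec.to_row())
            eq_r = float(np.sqrt(cell.area_um2 / np.pi))
            for role in corrected:
                avg = radial_average_image(
                    corrected[role], cell.centroid_xy, method=config.radial_method
                )
                prof = radial_profile(
                    avg,
                    cell.centroid_xy,
                    img.pixel_size_um,
                    config.bin_width_um,
                    channel=role,
                    equivalent_radius_um=eq_r,
                )
                profiles.append(prof)
                df = prof.to_dataframe()
                df.insert(0, "cell_id", cell.label_id)
                df.insert(0, "image", name)
                profile_rows.append(df)

    if not records:
        raise RuntimeError("zero cells segmented in every image; check the reference channel")

    per_cell = pd.DataFrame(records)
    per_cell_path = out / "per_cell.csv"
    per_cell.to_csv(per_cell_path, index=False)

    profile_path = out / "radial_profiles.csv"
    pd.concat(profile_rows, ignore_index=True).to_csv(profile_path, index=False)

    # cohort averaging per channel across cells (profiles are single-channel)
    by_channel: dict[str, list] = {}
    for p in profiles:
        by_channel.setdefault(next(iter(p.means)), []).append(p)
    cohort_rows = []
    for ch, plist in by_channel.items():
        cp = cohort_radial_average(plist, normalize_radius=True)
        df = cp.to_dataframe()
        df["channel"] = ch
        cohort_rows.append(df)
    cohort_path = out / "cohort_radial.csv"
    pd.concat(cohort_rows, ignore_index=True).to_csv(cohort_path, index=False)

    summary = aggregate(per_cell, group_by="experiment")
    summary_path = out / "summary.csv"
    summary.to_csv(summary_path, index=False)

    artifacts = {
        "per_cell": per_cell_path,
        "radial_profiles": profile_path,
        "cohort_radial": cohort_path,
        "summary": summary_path,
    }
    _write_manifest(out / "manifest.json", config, [n for n, _ in images], artifacts)
    artifacts["manifest"] = out / "manifest.json"
    return artifacts


def _load_or_generate_3d(config: PipelineConfig) -> list[tuple[str, VolumeStack]]:
    if config.inputs:
        return [(p, VolumeStack.from_tiff(p)) for p in config.inputs]
    stacks = []
    for i in range(config.n_demo):
        spec = StackSpec(seed=_derived_seed(config.seed, i))
        stack, _ = render_stack(spec)
        stacks.append((f"demo_3d_{i}", stack))
    return stacks


def run_3d_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the 3D confocal analysis; returns the paths of the written artifacts."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stacks = _load_or_generate_3d(config)
    for name, stack in stacks:
        _check_channels(stack, ["membrane", "cargo", "released_cargo"], config, name)
        ref_shape = stack.shape
        for ch, arr in stack.channels.items():
            if arr.shape != ref_shape:
                raise ValueError(f"{name}: channel {ch} voxel grid mismatch")

    object_rows = []
    cell_rows = []
    for name, stack in stacks:
        cell = build_cell_mask(stack, config.channels["membrane"], config.smoothing_um)
        internal = segment_vesicles(
            stack, config.channels["cargo"], cell, "internal", config.min_voxels
        )
        released = segment_vesicles(
            stack, config.channels["released_cargo"], cell, "released", config.min_voxels
        )
        logger.info("stack %s: %d internal, %d released", name, len(internal), len(released))
        for ves in (internal, released):
            df = ves.objects.copy()
            df.insert(0, "stack", name)
            object_rows.append(df)
        summ = per_cell_summary(internal, released, cell)
        cell_rows.append(
            {
                "stack": name,
                "n_internal": summ["n_internal"],
                "n_released": summ["n_released"],
                "cell_volume_um3": summ["cell_volume_um3"],
            }
        )

    objects_path = out / "vesicles.csv"
    pd.concat(object_rows, ignore_index=True).to_csv(objects_path, index=False)
    cells_path = out / "per_cell_3d.csv"
    pd.DataFrame(cell_rows).to_csv(cells_path, index=False)

    artifacts = {"vesicles": objects_path, "per_cell_3d": cells_path}
    _write_manifest(out / "manifest_3d.json", config, [n for n, _ in stacks], artifacts)
    artifacts["manifest"] = out / "manifest_3d.json"
    return artifacts


def _write_manifest(
    path: Path, config: PipelineConfig, inputs: list[str], artifacts: dict[str, Path]
) -> None:
    write_json(
        path,
        {
            "software": "synquant",
            "version": __version__,
            "seed": config.seed,
            "parameters": config.to_dict(),
            "inputs": inputs,
            "outputs": {k: str(v) for k, v in artifacts.items()},
        },
    )
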