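"""Pipeline orchestration: one validated config drives every analysis stage.

``run_pipeline`` executes descriptors → pocket volume → SASA/interface →
contacts → classification on a trajectory (or single structure), writing
per-frame CSV series, JSON summaries with a full parameter echo, and the
persistent-pocket maps.  Stage failures abort with the stage name.  All
unprinted-parameter defaults are echoed into the outputs so every choice is
visible in the provenance block.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .classification import (StateThresholds, classify_binding_mode,
                             classify_pocket_state, histogram_report)
from .contacts import contact_map, residence_profile
from .descriptors import (DescriptorSeries, com_distance, gg_inside_count,
                          insertion_depth, interhelix_angle)
from .pocket_volume import (GridSpec, persistent_pocket, pocket_grid_to_opendx,
                            pocket_grid_to_pdb, volume_series)
from .sasa_interface import interface_area, region_sasa
from .structure_io import (AtomSelection, RegionMap, Structure, Trajectory,
                           load_structure, load_trajectory, resolve_region)

__all__ = ["AnalysisConfig", "RunReport", "run_pipeline", "fetch_fixture",
           "FetchUnavailableError", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Config schema
# ---------------------------------------------------------------------------

class InputConfig(BaseModel):
    topology: str
    trajectory: Optional[str] = None
    format: Optional[str] = None
    frame_dt_ns: float = 1.0


class ChainConfig(BaseModel):
    rab: str = "A"
    gdi: str = "B"


class GridConfig(BaseModel):
    spacing: float = 1.0
    inclusion_radius: float = 12.0
    occupancy_padding: float = 1.09
    contiguity_min_neighbors: int = 3
    hull_constraint: bool = True
    center_region: str = "gdi_h1+gdi_h2+gdi_h3"


class SasaConfig(BaseModel):
    probe_radius: float = 1.4
    n_points: int = 960
    regions: list[str] = Field(default_factory=lambda: ["switch1", "switch2", "hvr"])


class ContactsConfig(BaseModel):
    cutoff: float = 3.0
    pairs: list[tuple[str, str]] = Field(default_factory=lambda: [
        ("gdi_rbp", "switch1+switch2"), ("gdi_ccr", "hvr")])


class ThresholdConfig(BaseModel):
    tight_max_dinter: float = 3.55
    open_min_theta: float = 40.0
    open_max_depth: float = 2.3
    volume_bands: tuple[float, float] = (250.0, 550.0)

    def to_thresholds(self) -> StateThresholds:
        return StateThresholds(**self.model_dump())


class AnalysisConfig(BaseModel):
    """Schema-validated pipeline configuration (YAML-loadable)."""

    input: InputConfig
    chains: ChainConfig = ChainConfig()
    regions: dict[str, object] = Field(default_factory=dict)
    grid: GridConfig = GridConfig()
    sasa: SasaConfig = SasaConfig()
    contacts: ContactsConfig = ContactsConfig()
    thresholds: ThresholdConfig = ThresholdConfig()
    discard_fraction: float = 0.2
    window: Optional[tuple[int, int]] = None
    gg_head_atom: str = "C20"
    gg_inside_cutoff_nm: float = 1.5
    persistence_fraction: float = 0.75
    stages: list[Literal["descriptors", "pocket", "sasa", "contacts", "classify"]] = \
        Field(default_factory=lambda: ["descriptors", "pocket", "sasa",
                                       "contacts", "classify"])
    output_dir: str = "prenylpocket_out"
    seed: int = 0

    @field_validator("discard_fraction")
    @classmethod
    def _frac(cls, v: float) -> float:
        if not 0.0 <= v < 1.0:
            raise ValueError("discard_fraction must be in [0, 1)")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.model_validate(data)

    def region_map(self) -> RegionMap:
        rm = RegionMap(self.regions)
        return rm.with_chain({"rab": self.chains.rab, "gdi": self.chains.gdi})

    def validate_regions(self) -> None:
        """Pre-flight check: pocket stage requires H2/H3 ranges (no default)."""
        if "pocket" in self.stages:
            rm = RegionMap(self.regions)
            for name in ("gdi_h2", "gdi_h3"):
                if name not in rm:
                    raise ValueError(
                        f"pocket stage enabled but region {name!r} is not "
                        "configured (it has no default range)")


class RunReport(dict):
    """JSON-serializable pipeline report (stage summaries + provenance)."""


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def resolve_combined(structure: Structure, regions: RegionMap, name: str,
                     atom_filter: str = "all",
                     include_hetero: bool = False) -> AtomSelection:
    """Resolve ``a+b+c`` region-name unions into one selection."""
    parts = name.split("+")
    indices = np.unique(np.concatenate([
        resolve_region(structure, regions, p, atom_filter, include_hetero).indices
        for p in parts]))
    return AtomSelection(structure, indices, label=name)


def _chain_selection(structure: Structure, chain: str, label: str,
                     include_hetero: bool = False) -> AtomSelection:
    mask = structure.chain_ids == chain
    if not include_hetero:
        mask &= ~structure.hetero
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"chain {chain!r} matched no atoms")
    return AtomSelection(structure, idx, label=label)


def _series_to_csv(series: DescriptorSeries, path: Path) -> None:
    import pandas as pd

    pd.DataFrame({
        "frame_time_ns": series.frame_times,
        "value": series.values,
        "unit": series.unit,
    }).to_csv(path, index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: AnalysisConfig,
                 trajectory: Trajectory | None = None,
                 regions: RegionMap | None = None) -> RunReport:
    """Run all configured stages; returns the report written to output_dir.

    ``trajectory``/``regions`` may be passed directly (e.g. synthetic
    fixtures); otherwise they are loaded from the config's input paths.
    """
    config.validate_regions()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    report["software"] = {"package": "prenylpocket", "version": __version__}
    report["config"] = json.loads(config.model_dump_json())
    checksums = {}
    if trajectory is None:
        top = Path(config.input.topology)
        if config.input.trajectory:
            trajectory = load_trajectory(top, config.input.trajectory,
                                         format=config.input.format,
                                         frame_dt=config.input.frame_dt_ns)
            checksums[str(config.input.trajectory)] = _sha256(Path(config.input.trajectory))
        else:
            struct = load_structure(top)
            trajectory = Trajectory(struct, struct.coordinates[None], np.array([0.0]))
        checksums[str(top)] = _sha256(top)
    report["input_checksums"] = checksums
    regions = regions if regions is not None else config.region_map()
    struct = trajectory.structure
    window = (tuple(config.window) if config.window
              else (int(np.floor(config.discard_fraction * trajectory.n_frames)),
                    trajectory.n_frames))
    report["window_frames"] = list(window)
    thresholds = config.thresholds.to_thresholds()

    series_store: dict[str, DescriptorSeries] = {}

    def stage(name):
        def deco(fn):
            if name not in config.stages:
                return None
            t0 = time.perf_counter()
            _log(f"[prenylpocket] stage {name} ...")
            try:
                result = fn()
            except Exception as exc:
                (out / "STALE").write_text(
                    f"pipeline aborted in stage {name}: {exc}\n")
                raise PipelineError(name, str(exc)) from exc
            _log(f"[prenylpocket] stage {name} done in "
                 f"{time.perf_counter() - t0:.2f} s")
            report[name] = result
            return result
        return deco

    @stage("descriptors")
    def _descriptors():
        rab_gdom = resolve_region(struct, regions, "rab_gdomain", "heavy")
        gdi_all = _chain_selection(struct, config.chains.gdi, "gdi")
        d_inter = com_distance(trajectory, rab_gdom, gdi_all)
        series_store["d_inter"] = d_inter
        h1 = resolve_region(struct, regions, "gdi_h1", "CA")
        summaries = {"d_inter": d_inter.summary()}
        if "gdi_h2" in regions:
            h2 = resolve_region(struct, regions, "gdi_h2", "CA")
            theta = interhelix_angle(trajectory, h1, h2)
            series_store["theta"] = theta
            summaries["theta"] = theta.summary()
        met = resolve_region(struct, regions, "gdi_met132", "CA")
        cys_sels = {}
        for res in regions.residues("gg_cys"):
            mask = ((struct.residue_numbers == res)
                    & (struct.atom_names == "CA") & ~struct.hetero
                    & (struct.chain_ids == config.chains.rab))
            idx = np.flatnonzero(mask)
            if idx.size == 1:
                cys_sels[res] = AtomSelection(struct, idx, f"Cys{res}")
        if cys_sels:
            depth = insertion_depth(trajectory, met, cys_sels)
            series_store.update(depth)
            summaries.update({k: v.summary() for k, v in depth.items()})
        head_mask = (struct.hetero & (struct.atom_names == config.gg_head_atom))
        head_idx = np.flatnonzero(head_mask)
        if head_idx.size:
            heads = AtomSelection(struct, head_idx, "gg_heads")
            inside = gg_inside_count(trajectory, met, heads,
                                     cutoff=config.gg_inside_cutoff_nm)
            series_store["n_gg_inside"] = inside
            summaries["n_gg_inside"] = inside.summary()
        for name, series in series_store.items():
            _series_to_csv(series, out / f"{name}.csv")
        return summaries

    @stage("pocket")
    def _pocket():
        gdi_sel = _chain_selection(struct, config.chains.gdi, "gdi_protein")
        heavy = gdi_sel.indices[struct.elements[gdi_sel.indices] != "H"]
        gdi_sel = AtomSelection(struct, heavy, "gdi_protein")
        center = resolve_combined(struct, regions, config.grid.center_region, "all")
        grid = GridSpec(
            spacing=config.grid.spacing,
            inclusion_spheres=[((0.0, 0.0, 0.0), config.grid.inclusion_radius)],
            occupancy_padding=config.grid.occupancy_padding,
            contiguity_min_neighbors=config.grid.contiguity_min_neighbors,
            hull_constraint=config.grid.hull_constraint,
        )
        series, mean, sd = volume_series(trajectory, gdi_sel, grid,
                                         window=window, center_sel=center)
        series_store["pocket_volume"] = series
        _series_to_csv(series, out / "pocket_volume.csv")
        persistent = persistent_pocket(trajectory, gdi_sel, grid,
                                       fraction=config.persistence_fraction,
                                       window=window, center_sel=center)
        pocket_grid_to_pdb(persistent, out / "persistent_pocket.pdb")
        pocket_grid_to_opendx(persistent, out / "persistent_pocket.dx")
        return {"mean_A3": mean, "sd_A3": sd,
                "persistent_volume_A3": persistent.volume,
                "persistence_fraction": config.persistence_fraction,
                "grid": config.grid.model_dump()}

    @stage("sasa")
    def _sasa():
        available = [r for r in config.sasa.regions if r in regions]
        result = {}
        if available:
            series = region_sasa(trajectory, regions, available, window=window,
                                 probe=config.sasa.probe_radius,
                                 n_points=config.sasa.n_points)
            for name, s in series.items():
                _series_to_csv(s, out / f"{name}.csv")
                result[name] = s.summary()
        rab = _chain_selection(struct, config.chains.rab, "rab")
        gdi = _chain_selection(struct, config.chains.gdi, "gdi")
        mid_frame = trajectory.frames[(window[0] + window[1] - 1) // 2]
        buried = interface_area(mid_frame, rab, gdi,
                                probe=config.sasa.probe_radius,
                                n_points=config.sasa.n_points)
        result["interface_area"] = {"unhalved_A2": buried,
                                    "halved_A2": buried / 2.0}
        return result

    @stage("contacts")
    def _contacts():
        result = {}
        for name_a, name_b in config.contacts.pairs:
            try:
                sel_a = resolve_combined(struct, regions, name_a, "heavy")
                sel_b = resolve_combined(struct, regions, name_b, "heavy")
            except KeyError as exc:
                raise ValueError(f"contact pair ({name_a}, {name_b}): {exc}")
            cmap = contact_map(trajectory, sel_a, sel_b,
                               cutoff=config.contacts.cutoff, window=window)
            profile = residence_profile(cmap)
            key = f"{name_a}__vs__{name_b}"
            profile.to_frame().to_csv(out / f"contacts_{key}.csv", index=False)
            result[key] = {
                "n_residues_in_contact": int((profile.occupancy_fraction > 0).sum()),
                "max_residence_ns": float(profile.residence_ns.max()),
                "window_span_ns": profile.window_span_ns,
            }
        return result

    @stage("classify")
    def _classify():
        result = {}
        if "d_inter" in series_store:
            d = series_store["d_inter"]
            sub = DescriptorSeries(d.name, d.values[window[0]:window[1]],
                                   d.unit, d.frame_times[window[0]:window[1]])
            binding = classify_binding_mode(sub, thresholds)
            result["binding"] = {"majority": binding.majority,
                                 "fractions": binding.fractions}
            histogram_report(sub, bin_width=0.01,
                             plot_path=out / "d_inter_hist.svg"
                             ).to_csv(out / "d_inter_hist.csv", index=False)
        if "pocket_volume" in series_store:
            theta = series_store.get("theta")
            depth = series_store.get("d_GGpocket_mean")

            def crop(s):
                if s is None or len(s) == len(series_store["pocket_volume"]):
                    return s
                return DescriptorSeries(s.name, s.values[window[0]:window[1]],
                                        s.unit, s.frame_times[window[0]:window[1]])
            pocket = classify_pocket_state(series_store["pocket_volume"],
                                           crop(theta), crop(depth), thresholds)
            result["pocket"] = {"majority": pocket.majority,
                                "fractions": pocket.fractions}
            if pocket.concordant is not None:
                result["pocket"]["concordance_fraction"] = float(
                    pocket.concordant.mean())
        return result

    report["thresholds"] = asdict(thresholds)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    stale = out / "STALE"
    if stale.exists():
        stale.unlink()
    return report


# ---------------------------------------------------------------------------
# PDB fixture fetching (cache-first; skippable offline)
# ---------------------------------------------------------------------------

class FetchUnavailableError(OSError):
    """Raised when a PDB entry is neither cached nor downloadable."""


def fetch_fixture(pdb_id: str, cache_dir: str | Path = "fixtures/pdb_cache",
                  timeout: float = 30.0) -> Path:
    """Return a cached PDB file for ``pdb_id``, downloading if necessary.

    Cache-first: a present file is returned without network access and its
    checksum recorded alongside.  Download failures raise
    :class:`FetchUnavailableError`; callers in test mode should skip on it.
    """
    pdb_id = pdb_id.strip().upper()
    if len(pdb_id) != 4 or not pdb_id.isalnum():
        raise ValueError(f"invalid PDB id {pdb_id!r}")
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"{pdb_id}.pdb"
    if path.exists():
        return path
    url = f"https://files.rcsb.org/download/{pdb_id}.pdb"
    import urllib.error
    import urllib.request

    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            data = resp.read()
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise FetchUnavailableError(
            f"PDB entry {pdb_id} is not cached at {path} and could not be "
            f"downloaded ({exc})") from exc
    path.write_bytes(data)
    (cache_dir / f"{pdb_id}.sha256").write_text(_sha256(path) + "\n")
    return path
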