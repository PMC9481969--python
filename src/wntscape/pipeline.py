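"""End-to-end orchestration: catalogue -> tables -> occupancy -> ROHOs ->
unique/zero territories -> networks -> exports.

One configuration (YAML/JSON or :class:`RunConfig`) drives the whole
analysis and writes a stable output layout::

    out_dir/
      tables/     pairwise tables (all four modes), anatomy proportions
      volumes/    occupancy, labelled ROHOs, peaks, unique and zero masks
      networks/   thresholded JI networks (GraphML) + combination counts
      summary.json

Defaults reproduce the published analysis parameters (ROHO thresholds
Wnt 5/4/5 at E9.5/E10.5/E11.5, Fzd 4; peaks Wnt 7, Fzd 6; 26-connectivity;
top-15 network threshold selection).  For phantom runs the ROHO threshold
defaults to the phantom's genes-per-hotspot, so planted hotspots are the
detection target.  Runs are deterministic given the configuration:
identical config (including seed) gives byte-identical CSV/GraphML
artefacts; wall-clock time lives only in the summary.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .domains import DomainCatalog, VoxelGrid
from .domain_io import export_table, read_catalog, write_network, write_volume
from .errors import ValidationError, WntscapeError
from .occupancy_analysis import (
    DEFAULT_PEAK_THRESHOLDS,
    DEFAULT_ROHO_THRESHOLDS,
    occupancy_map,
    occupancy_peaks,
    roho_gene_sets,
    roho_table,
    threshold_regions,
    unique_gene_domains,
    zero_expression_domain,
)
from .similarity_networks import (
    MAX_COMBINATION_GENES,
    build_network,
    combination_counts,
    select_topk_threshold,
)
from .synthetic_embryo import PhantomConfig, generate_catalog
from .volumetrics import TABLE_MODES, anatomy_proportions, pairwise_table

logger = logging.getLogger(__name__)

_CONNECTIVITIES = (6, 18, 26)


@dataclass
class RunConfig:
    """One pipeline run: exactly one of ``manifest`` / ``phantom`` as input."""

    out_dir: Path
    manifest: Path | None = None
    phantom: PhantomConfig | None = None
    families: list[str] | None = None  # None: every family in the catalogue
    stages: list[str] | None = None  # None: every stage in the catalogue
    roho_thresholds: dict[str, dict[str, int] | int] = field(default_factory=dict)
    peak_thresholds: dict[str, int] = field(default_factory=dict)
    connectivity: int = 26
    min_voxels: int = 5
    network_k: int = 15
    seed: int = 0
    restrict_to_embryo: bool = False
    volume_format: str = "nifti"

    def problems(self) -> list[str]:
        """All configuration problems, without executing anything."""
        out: list[str] = []
        if (self.manifest is None) == (self.phantom is None):
            out.append("exactly one of 'manifest' and 'phantom' must be present")
        if self.manifest is not None and not Path(self.manifest).exists():
            out.append(f"manifest not found: {self.manifest}")
        if self.phantom is not None:
            try:
                self.phantom.validate()
            except ValidationError as exc:
                out.append(f"phantom: {exc}")
        if self.network_k < 1:
            out.append(f"network_k must be >= 1, got {self.network_k}")
        if self.connectivity not in _CONNECTIVITIES:
            out.append(f"connectivity must be one of {_CONNECTIVITIES}, got {self.connectivity}")
        if self.min_voxels < 1:
            out.append(f"min_voxels must be >= 1, got {self.min_voxels}")
        for fam, entry in self.roho_thresholds.items():
            values = entry.values() if isinstance(entry, dict) else [entry]
            if any((not isinstance(v, int)) or v < 1 for v in values):
                out.append(f"roho threshold for {fam!r} must be a positive integer")
        for fam, v in self.peak_thresholds.items():
            if (not isinstance(v, int)) or v < 1:
                out.append(f"peak threshold for {fam!r} must be a positive integer")
        if self.volume_format not in ("nifti", "tiff"):
            out.append(f"volume_format must be 'nifti' or 'tiff', got {self.volume_format}")
        return out

    def roho_threshold(self, family: str, stage: str) -> int | None:
        entry = self.roho_thresholds.get(family)
        if isinstance(entry, dict):
            value = entry.get(stage, entry.get("all"))
            if value is not None:
                return int(value)
        elif entry is not None:
            return int(entry)
        if self.phantom is not None:
            return int(self.phantom.genes_per_hotspot)
        default = DEFAULT_ROHO_THRESHOLDS.get(family)
        if default is not None:
            return default.get(stage, max(default.values()))
        return None

    def peak_threshold(self, family: str) -> int | None:
        if family in self.peak_thresholds:
            return int(self.peak_thresholds[family])
        return DEFAULT_PEAK_THRESHOLDS.get(family)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML or JSON run configuration."""
    path = Path(path)
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: configuration must be a mapping")
    phantom = None
    if doc.get("phantom") is not None:
        pdoc = dict(doc["phantom"])
        if "grid" in pdoc:
            pdoc["grid"] = VoxelGrid(**pdoc["grid"])
        phantom = PhantomConfig(**pdoc)
    known = {f.name for f in RunConfig.__dataclass_fields__.values()}
    extra = set(doc) - known
    if extra:
        raise ValidationError(f"{path}: unknown configuration keys {sorted(extra)}")
    kwargs = {k: v for k, v in doc.items() if k in known and k != "phantom"}
    if "manifest" in kwargs and kwargs["manifest"] is not None:
        m = Path(kwargs["manifest"])
        kwargs["manifest"] = m if m.is_absolute() else path.parent / m
    kwargs["out_dir"] = Path(kwargs.get("out_dir", path.parent / "wntscape_out"))
    return RunConfig(phantom=phantom, **kwargs)


def validate(config: RunConfig | str | Path) -> list[str]:
    """Validation report: a list of problems (empty when valid)."""
    if not isinstance(config, RunConfig):
        config = load_config(config)
    return config.problems()


@dataclass
class RunSummary:
    """Machine-readable record of one pipeline run."""

    config: dict
    version: str
    grid_shape: tuple[int, int, int]
    voxel_size_um: tuple[float, float, float]
    analyses: dict = field(default_factory=dict)
    error: str | None = None
    wall_time_s: float = 0.0

    def to_json(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def _load_or_generate(config: RunConfig) -> DomainCatalog:
    if config.phantom is not None:
        catalog, _ = generate_catalog(config.phantom)
        return catalog
    return read_catalog(config.manifest)


def _vol_ext(config: RunConfig) -> str:
    return ".nii.gz" if config.volume_format == "nifti" else ".tif"


def run(config: RunConfig) -> RunSummary:
    """Execute the full analysis; write artefacts and summary.json.

    Any stage failure aborts with the stage name; the partial summary
    stub (including the error) is still written.
    """
    t0 = time.monotonic()
    problems = config.problems()
    if problems:
        raise ValidationError("invalid configuration: " + "; ".join(problems))
    out_dir = Path(config.out_dir)
    for sub in ("tables", "volumes", "networks"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)

    stage_name = "load_catalog"
    summary = RunSummary(
        config={k: str(v) if isinstance(v, Path) else v
                for k, v in asdict(config).items()},
        version=__version__,
        grid_shape=(0, 0, 0),
        voxel_size_um=(0.0, 0.0, 0.0),
    )
    try:
        catalog = _load_or_generate(config)
        summary.grid_shape = catalog.grid.shape
        summary.voxel_size_um = catalog.grid.voxel_size_um

        families = config.families or [
            f for f in catalog.families if f not in ("reporter",)
        ]
        stages = config.stages or catalog.stages
        ext = _vol_ext(config)
        vsize = catalog.grid.voxel_size_um

        for family in families:
            for stage in stages:
                domains = catalog.select(family=family, stage=stage)
                if not domains:
                    raise ValidationError(
                        f"no domains for requested family {family!r} at stage {stage!r}"
                    )
                tag = f"{family}_{stage}".replace(" ", "_")
                entry: dict = {
                    "n_genes": len(domains),
                    "volumes_voxels": {d.label: d.volume_voxels for d in domains},
                    "files": {},
                }

                stage_name = f"tables[{tag}]"
                for mode in TABLE_MODES:
                    table = pairwise_table(
                        catalog, family=family, stage=stage, mode=mode,
                        restrict_to_embryo=config.restrict_to_embryo,
                    )
                    fpath = out_dir / "tables" / f"{tag}_{mode}.csv"
                    export_table(table, fpath)
                    entry["files"][mode] = str(fpath)
                jaccard_table = pairwise_table(catalog, family=family, stage=stage,
                                               mode="jaccard")

                stage_name = f"occupancy[{tag}]"
                occ = occupancy_map(catalog, family=family, stage=stage)
                occ_path = out_dir / "volumes" / f"occupancy_{tag}{ext}"
                write_volume(occ.counts, occ_path, vsize)
                entry["files"]["occupancy"] = str(occ_path)
                entry["max_occupancy"] = occ.max_occupancy

                stage_name = f"roho[{tag}]"
                t = config.roho_threshold(family, stage)
                if t is None:
                    t = min(4, occ.n_genes)
                    logger.warning(
                        "no ROHO threshold configured for %s/%s; using %d", family, stage, t
                    )
                if t > occ.n_genes:
                    logger.warning(
                        "ROHO threshold %d exceeds %d genes for %s/%s; capping",
                        t, occ.n_genes, family, stage,
                    )
                    t = occ.n_genes
                regions = threshold_regions(
                    occ, t, connectivity=config.connectivity, min_voxels=config.min_voxels
                )
                records = roho_gene_sets(regions, catalog)
                labels_path = out_dir / "volumes" / f"roho_labels_{tag}{ext}"
                write_volume(regions.labels, labels_path, vsize)
                table_path = out_dir / "tables" / f"roho_{tag}.csv"
                roho_table(records).to_csv(table_path, index=False)
                entry["roho"] = {
                    "threshold": t,
                    "count": regions.n_regions,
                    "records": [
                        {
                            "id": r.id,
                            "voxels": r.voxel_count,
                            "volume_um3": r.volume_um3,
                            "peak_occupancy": r.peak_occupancy,
                            "gene_set": sorted(r.gene_set),
                        }
                        for r in records
                    ],
                }
                entry["files"]["roho_labels"] = str(labels_path)
                entry["files"]["roho_table"] = str(table_path)

                stage_name = f"peaks[{tag}]"
                peak_t = config.peak_threshold(family)
                if peak_t is not None:
                    peaks = occupancy_peaks(occ, peak_t)
                    peaks_path = out_dir / "volumes" / f"peaks_{tag}{ext}"
                    write_volume(peaks.mask, peaks_path, vsize)
                    entry["peaks"] = {"threshold": peak_t, "voxels": peaks.volume_voxels}
                    entry["files"]["peaks"] = str(peaks_path)

                stage_name = f"unique[{tag}]"
                if len(domains) >= 2:
                    uniques, contrib = unique_gene_domains(catalog, family=family, stage=stage)
                    contrib_path = out_dir / "tables" / f"unique_{tag}.csv"
                    contrib.to_csv(contrib_path)
                    entry["unique"] = {
                        "single_gene_voxels": int(contrib["unique_voxels"].sum()),
                    }
                    entry["files"]["unique_table"] = str(contrib_path)

                stage_name = f"zero[{tag}]"
                if catalog.embryo_mask is not None:
                    zero = zero_expression_domain(catalog, family=family, stage=stage)
                    zero_path = out_dir / "volumes" / f"zero_{tag}{ext}"
                    write_volume(zero.mask, zero_path, vsize)
                    entry["zero"] = {
                        "voxels": zero.volume_voxels,
                        "fraction_of_embryo": (
                            zero.volume_voxels / catalog.embryo_mask.volume_voxels
                        ),
                    }
                    entry["files"]["zero"] = str(zero_path)

                stage_name = f"network[{tag}]"
                k = min(config.network_k, len(domains))
                threshold = select_topk_threshold(jaccard_table, k)
                network = build_network(jaccard_table, threshold)
                net_path = out_dir / "networks" / f"network_{tag}.graphml"
                write_network(network, net_path)
                entry["network"] = {
                    "k": k,
                    "threshold": threshold,
                    "k_retained": network.k_retained,
                    "n_edges": network.graph.number_of_edges(),
                }
                entry["files"]["network"] = str(net_path)

                stage_name = f"combinations[{tag}]"
                if catalog.embryo_mask is not None and len(domains) <= MAX_COMBINATION_GENES:
                    combos = combination_counts(catalog, family=family, stage=stage)
                    combo_path = out_dir / "networks" / f"combinations_{tag}.csv"
                    combos.to_csv(combo_path, index=False)
                    entry["files"]["combinations"] = str(combo_path)

                stage_name = f"anatomy[{tag}]"
                if catalog.anatomy is not None:
                    props = anatomy_proportions(catalog, family=family, stage=stage)
                    prop_path = out_dir / "tables" / f"anatomy_proportions_{tag}.csv"
                    props.to_csv(prop_path)
                    entry["files"]["anatomy_proportions"] = str(prop_path)

                summary.analyses[tag] = entry
    except Exception as exc:
        summary.error = f"stage {stage_name}: {exc}"
        summary.wall_time_s = time.monotonic() - t0
        summary.to_json(out_dir / "summary.json")
        if isinstance(exc, WntscapeError):
            raise type(exc)(f"stage {stage_name}: {exc}") from exc
        raise

    summary.wall_time_s = time.monotonic() - t0
    summary.to_json(out_dir / "summary.json")
    return summary
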