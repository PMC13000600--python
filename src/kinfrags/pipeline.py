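"""Configuration-driven orchestration of the full curation cascade.

Default cascade: prefilter -> PAINS -> Brenk -> Ro3 -> QED -> building
blocks -> synthesizability score -> retrosynthesis gate.  Every filter is
optional and reorderable.  Fragment-level filters are computed as
independent pass flags on the prefiltered library and then intersected, so
independent-mode and sequential reports come from one pass; the
retrosynthesis gate runs last, only on fragments passing everything else
(pairs are expensive to query).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .analysis import FilterReport, build_reports
from .catalogs import filter_unwanted, load_catalog
from .core import DEFAULT_ADJACENCY, FragmentLibrary, read_library, write_library
from .pairs import RetroBackend, enumerate_valid_pairs, filter_retro
from .prefilter import PrefilterReport, prefilter
from .properties import DEFAULT_QED_THRESHOLD, Ro3Config, filter_properties
from .synth import BuildingBlockIndex, SybaModel, filter_building_blocks, filter_syba

logger = logging.getLogger(__name__)

FRAGMENT_FILTERS = ("pains", "brenk", "ro3", "qed", "building_blocks", "syba")
DEFAULT_ORDER = FRAGMENT_FILTERS + ("retro",)


@dataclass
class PipelineConfig:
    """Filter selection, ordering and parameters for one pipeline run.

    Unknown keys in a config file are rejected.  The defaults reproduce the
    full default cascade.
    """

    filters: tuple[str, ...] = DEFAULT_ORDER
    dedup_key: str = "inchi"
    pains_catalog: str = "pains"
    brenk_catalog: str = "brenk"
    ro3_max_mismatches: int = 0
    ro3_hba_definition: str = "lipinski"
    qed_threshold: float = DEFAULT_QED_THRESHOLD
    qed_weights: str = "mean"
    syba_cutoff: float = 0.0
    syba_model_path: str = ""
    building_blocks_path: str = ""
    retro_url: str = ""
    retro_timeout: float = 30.0
    retro_keep_unpaired: bool = False
    retro_skip_on_unavailable: bool = False
    retro_cache_path: str = ""
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [f for f in self.filters if f not in DEFAULT_ORDER]
        if unknown:
            raise ValueError(f"unknown filters in cascade: {unknown}")

    @classmethod
    def from_dict(cls, payload: Mapping[str, Any]) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        payload = dict(payload)
        if "filters" in payload:
            payload["filters"] = tuple(payload["filters"])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        """Stable hash recorded in all outputs: identical config, identical runs."""
        canonical = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything one cascade run produced."""

    library: FragmentLibrary  # final filtered library
    prefiltered: FragmentLibrary
    prefilter_report: PrefilterReport
    flags: pd.DataFrame  # independent pass flags on the prefiltered library
    report: FilterReport | None
    audit: pd.DataFrame  # per-fragment, per-filter decisions
    config_hash: str
    undetermined_retro: list[str] = field(default_factory=list)


def compute_flags(
    library: FragmentLibrary,
    config: PipelineConfig,
    bb_index: BuildingBlockIndex | None = None,
    syba_model: SybaModel | None = None,
) -> pd.DataFrame:
    """Independent pass flags for the enabled fragment-level filters."""
    enabled = [f for f in config.filters if f in FRAGMENT_FILTERS]
    columns: list[pd.DataFrame] = []
    catalogs = []
    if "pains" in enabled:
        catalogs.append(load_catalog(config.pains_catalog))
    if "brenk" in enabled:
        catalogs.append(load_catalog(config.brenk_catalog))
    if catalogs:
        columns.append(filter_unwanted(library, catalogs))
    if "ro3" in enabled or "qed" in enabled:
        props = filter_properties(
            library,
            Ro3Config(
                max_mismatches=config.ro3_max_mismatches,
                hba_definition=config.ro3_hba_definition,
            ),
            qed_threshold=config.qed_threshold,
            qed_weights=config.qed_weights,
        )
        keep = [c for c in ("ro3", "qed") if c in enabled]
        columns.append(props[keep])
    if "building_blocks" in enabled:
        if bb_index is None:
            if not config.building_blocks_path:
                raise ValueError("building-block filter enabled but no block set given")
            bb_index = BuildingBlockIndex.from_file(config.building_blocks_path)
        columns.append(filter_building_blocks(library, bb_index))
    if "syba" in enabled:
        if syba_model is None:
            if not config.syba_model_path:
                raise ValueError("syba filter enabled but no model given")
            syba_model = SybaModel.load(config.syba_model_path)
        columns.append(filter_syba(library, syba_model, cutoff=config.syba_cutoff))
    if not columns:
        return pd.DataFrame(index=range(len(library)))
    flags = pd.concat(columns, axis=1)
    # order columns along the cascade
    ordered = [c for c in enabled if c in flags.columns]
    return flags[ordered]


def run_pipeline(
    config: PipelineConfig,
    library: FragmentLibrary | None = None,
    library_path: str | Path | None = None,
    bb_index: BuildingBlockIndex | None = None,
    syba_model: SybaModel | None = None,
    retro_backend: RetroBackend | None = None,
    adjacency: frozenset[frozenset[str]] = DEFAULT_ADJACENCY,
    output_dir: str | Path | None = None,
) -> PipelineResult:
    """Run prefilter + the configured cascade; optionally write all outputs.

    Every removal decision is traceable in the per-fragment audit table.
    When the retrosynthesis gate is enabled but no backend is available the
    run halts before that stage unless ``retro_skip_on_unavailable`` is set.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if library is None:
        if library_path is None:
            raise ValueError("either a library or a library path is required")
        library, rejects = read_library(library_path)
        if len(rejects):
            logger.warning("%d records rejected while reading the library", len(rejects))

    prefiltered, prefilter_report = prefilter(library, dedup_key=config.dedup_key)
    flags = compute_flags(prefiltered, config, bb_index=bb_index, syba_model=syba_model)

    undetermined: list[str] = []
    retro_enabled = "retro" in config.filters
    if retro_enabled:
        if retro_backend is None and not config.retro_url:
            if config.retro_skip_on_unavailable:
                logger.warning("retro backend unavailable; skipping the retro gate")
                retro_enabled = False
            else:
                raise RuntimeError(
                    "retro gate enabled but no backend available "
                    "(set retro_skip_on_unavailable to bypass)"
                )
        if retro_enabled:
            if retro_backend is None:
                from .pairs import HttpRetroBackend

                retro_backend = HttpRetroBackend(config.retro_url, timeout=config.retro_timeout)
            pairs = enumerate_valid_pairs(prefiltered, adjacency, prior_flags=flags)
            gate = filter_retro(
                prefiltered,
                pairs,
                retro_backend,
                keep_unpaired=config.retro_keep_unpaired,
                cache_path=config.retro_cache_path or None,
            )
            undetermined = gate.undetermined
            flags = pd.concat([flags, gate.flags], axis=1)

    surviving = flags.all(axis=1) if len(flags.columns) else pd.Series(
        True, index=range(len(prefiltered))
    )
    final = prefiltered.subset(list(surviving))
    fragment_filter_cols = [c for c in flags.columns if c != "retro"]
    report = build_reports(prefiltered, flags[fragment_filter_cols]) if fragment_filter_cols else None

    audit = prefiltered.to_frame().reset_index(drop=True)
    audit = pd.concat([audit, flags.add_prefix("pass_")], axis=1)
    audit["survives"] = surviving.to_numpy()
    audit["config_hash"] = config.config_hash()

    result = PipelineResult(
        library=final,
        prefiltered=prefiltered,
        prefilter_report=prefilter_report,
        flags=flags,
        report=report,
        audit=audit,
        config_hash=config.config_hash(),
        undetermined_retro=undetermined,
    )
    if output_dir is not None:
        _write_outputs(result, Path(output_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_library(result.library, out / "filtered_library.sdf")
    write_library(result.library, out / "filtered_library.csv")
    result.audit.to_csv(out / "audit.csv", index=False)
    result.prefilter_report.removed.to_csv(out / "prefilter_report.csv")
    if result.report is not None:
        result.report.independent_removed.to_csv(out / "independent_removed.csv")
        result.report.sequential_remaining.to_csv(out / "sequential_remaining.csv")
        result.report.overlap.to_csv(out / "filter_overlap.csv")
    summary = {
        "config_hash": result.config_hash,
        "n_input_prefiltered": len(result.prefiltered),
        "n_final": len(result.library),
        "final_pool_sizes": result.library.sizes(),
        "undetermined_retro": result.undetermined_retro,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
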