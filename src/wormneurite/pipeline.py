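"""Batch processing: directories of SWC/TIFF inputs to feature tables and stats.

One neuron = one SWC file (plus an optional TIFF stack for ALM soma
volume).  File names following the ``STRAIN_SERIES_AGE_NEURON#`` labeling
scheme (e.g. ``WT_A_8_PLM01.swc``) are parsed for group metadata; a
manifest CSV can override the parsed fields.  Failures in one neuron never
abort the batch: the row is flagged and the error logged with its stage.

Cohort statistics: per-group means with bootstrap 95% CIs, the
bend-outgrowth association test, and KS comparisons of bend position
distributions between groups.  Outputs are deterministic under a fixed
config and seed, and every output records the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import (
    ClassifyConfig,
    NodeLabel,
    branch_inventory,
    classify_alm,
    classify_plm,
)
from .morphometry import (
    MainBranchGeometry,
    MorphConfig,
    bend_density,
    detect_beads,
    detect_bends,
    threshold_sweep,
)
from .soma_volume import ImageStack, SegmentConfig, segment_soma
from .spatial_stats import (
    EventPositions,
    association_test,
    bootstrap_ci_mean,
    ks_two_sample,
    positions_from_distal,
)
from .swc_io import read_swc

__all__ = [
    "RunConfig",
    "NeuronSummary",
    "parse_neuron_name",
    "process_neuron",
    "process_cohort",
]

logger = logging.getLogger(__name__)

_NAME_RE = re.compile(
    r"(?P<strain>[^_]+)_(?P<series>[^_]+)_(?P<age>[^_]+)_"
    r"(?P<neuron>(?P<neuron_class>ALM|PLM)[^.]*)"
)


@dataclass(frozen=True)
class RunConfig:
    """All pipeline thresholds in one place (documented defaults)."""

    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    morph: MorphConfig = field(default_factory=MorphConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    voxel_dims: tuple[float, float, float] = (0.223, 0.223, 0.300)
    swc_in_voxel_units: bool = False
    interaction_distance: float = 1.0
    n_boot: int = 2000
    rng_seed: int = 0

    @property
    def unit_scale(self) -> tuple[float, float, float]:
        return self.voxel_dims if self.swc_in_voxel_units else (1.0, 1.0, 1.0)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class NeuronSummary:
    """One quantified row per neuron."""

    neuron_id: str
    neuron_class: str
    strain: str = ""
    age: str = ""
    main_length_um: float = float("nan")
    soma_volume_um3: float = float("nan")
    soma_outgrowth_count: int = 0
    soma_outgrowth_length_um: float = 0.0
    neurite_outgrowth_count: int = 0
    neurite_outgrowth_length_um: float = 0.0
    bend_count: int = 0
    bend_density_per_um: float = float("nan")
    bead_count: int = 0
    bead_density_per_um: float = float("nan")
    error: str = ""
    config_hash: str = ""
    version: str = __version__


def parse_neuron_name(name: str) -> dict[str, str]:
    """Parse ``STRAIN_SERIES_AGE_NEURON#`` from a file name.

    Returns empty fields (and no neuron class) when the name does not
    follow the scheme.
    """
    m = _NAME_RE.match(Path(name).stem)
    if not m:
        return {"strain": "", "series": "", "age": "", "neuron": "",
                "neuron_class": ""}
    return m.groupdict()


def process_neuron(
    swc_path: str | Path,
    tiff_path: str | Path | None = None,
    cfg: RunConfig | None = None,
    neuron_class: str | None = None,
) -> tuple[NeuronSummary, EventPositions | None]:
    """Quantify one neuron: read, classify, detect events, segment soma.

    ``neuron_class`` overrides the class parsed from the file name.
    Errors are captured in the summary's ``error`` field (with the failing
    stage) rather than raised, so batches keep going.
    """
    cfg = cfg or RunConfig()
    meta = parse_neuron_name(str(swc_path))
    ncls = (neuron_class or meta["neuron_class"] or "").upper()
    summary = NeuronSummary(
        neuron_id=Path(swc_path).stem,
        neuron_class=ncls,
        strain=meta["strain"],
        age=meta["age"],
        config_hash=cfg.config_hash(),
    )
    stage = "read"
    try:
        tree = read_swc(swc_path, unit_scale=cfg.unit_scale)
        stage = "classify"
        if ncls == "ALM":
            ct = classify_alm(tree, cfg.classify)
        elif ncls == "PLM":
            ct = classify_plm(tree, cfg.classify)
        else:
            raise ValueError(
                f"neuron class not inferable from {swc_path!r}; pass "
                "neuron_class='ALM' or 'PLM'"
            )
        stage = "inventory"
        branches = branch_inventory(ct)
        soma_out = [b for b in branches if b.label == NodeLabel.SOMA_OUTGROWTH]
        neur_out = [b for b in branches if b.label == NodeLabel.NEURITE_OUTGROWTH]
        summary.main_length_um = ct.main_length
        summary.soma_outgrowth_count = len(soma_out)
        summary.soma_outgrowth_length_um = float(sum(b.length for b in soma_out))
        summary.neurite_outgrowth_count = len(neur_out)
        summary.neurite_outgrowth_length_um = float(
            sum(b.length for b in neur_out)
        )

        stage = "morphometry"
        geom = MainBranchGeometry.from_classified(ct)
        bends = detect_bends(geom, cfg.morph)
        beads = detect_beads(geom, cfg.morph)
        summary.bend_count = len(bends)
        summary.bend_density_per_um = bend_density(bends, ct.main_length)
        summary.bead_count = len(beads)
        summary.bead_density_per_um = bend_density(beads, ct.main_length)

        if ncls == "ALM" and tiff_path is not None:
            stage = "soma_volume"
            stack = ImageStack.from_tiff(tiff_path, voxel_dims=cfg.voxel_dims)
            summary.soma_volume_um3 = segment_soma(stack, ct, cfg.segment).volume

        positions = positions_from_distal(ct, bends, neur_out)
        positions.neuron_id = summary.neuron_id
        return summary, positions
    except Exception as exc:  # noqa: BLE001 - batch resilience by contract
        logger.error("%s failed at stage %s: %s", swc_path, stage, exc)
        summary.error = f"{stage}: {exc}"
        return summary, None


def _group_stats(
    df: pd.DataFrame, positions: dict[str, EventPositions], cfg: RunConfig
) -> dict:
    """Per-group means with bootstrap CIs, association and KS tests."""
    rng_seed = cfg.rng_seed
    stats: dict = {"groups": {}, "comparisons": {}}
    groups = sorted(df["group"].unique())
    for g in groups:
        sub = df[(df["group"] == g) & (df["error"] == "")]
        entry: dict = {"n": int(len(sub))}
        for col in (
            "bend_density_per_um",
            "bead_density_per_um",
            "neurite_outgrowth_count",
            "soma_outgrowth_count",
            "main_length_um",
        ):
            vals = sub[col].dropna().to_numpy()
            if len(vals) >= 2:
                lo, hi = bootstrap_ci_mean(
                    vals, n_boot=cfg.n_boot, seed=rng_seed
                )
                entry[col] = {
                    "mean": float(vals.mean()),
                    "ci95": [lo, hi],
                }
            elif len(vals) == 1:
                entry[col] = {"mean": float(vals[0]), "ci95": None}
        cohort = [
            positions[i] for i in sub["neuron_id"] if i in positions
        ]
        usable = [
            ep for ep in cohort
            if ep.bend_positions.size and ep.outgrowth_positions.size
        ]
        if len(usable) >= 2:
            res = association_test(usable, r=cfg.interaction_distance)
            entry["association"] = {
                "r_um": cfg.interaction_distance,
                "n_neurons": res.n_neurons,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "mean_observed_fraction": float(res.observed_fractions.mean()),
                "mean_expected_fraction": float(res.expected_fractions.mean()),
            }
        stats["groups"][g] = entry

    # KS comparisons of pooled relative bend positions between groups
    pooled = {}
    for g in groups:
        sub = df[(df["group"] == g) & (df["error"] == "")]
        pts = np.concatenate(
            [
                positions[i].bend_positions / positions[i].main_length
                for i in sub["neuron_id"]
                if i in positions and positions[i].bend_positions.size
            ]
            or [np.array([])]
        )
        pooled[g] = pts
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            if pooled[a].size and pooled[b].size:
                d, p = ks_two_sample(pooled[a], pooled[b])
                stats["comparisons"][f"{a}_vs_{b}"] = {
                    "ks_statistic": d,
                    "p_value": p,
                    "n_a": int(pooled[a].size),
                    "n_b": int(pooled[b].size),
                }
    return stats


def process_cohort(
    input_dir: str | Path,
    cfg: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Process every SWC file under ``input_dir``; optional TIFF siblings.

    Returns the per-neuron table and the cohort statistics dict; when
    ``out_dir`` is given, writes ``summary.csv`` and ``stats.json``.
    Groups are ``strain_age`` parsed from file names (``ungrouped`` when
    unparseable).  Deterministic under a fixed config.
    """
    cfg = cfg or RunConfig()
    input_dir = Path(input_dir)
    swc_files = sorted(input_dir.glob("*.swc"))
    if not swc_files:
        raise ValueError(f"no SWC files in {input_dir}")
    rows = []
    positions: dict[str, EventPositions] = {}
    for swc in swc_files:
        tiff = swc.with_suffix(".tif")
        summary, pos = process_neuron(
            swc, tiff if tiff.exists() else None, cfg
        )
        rows.append(dataclasses.asdict(summary))
        if pos is not None:
            positions[summary.neuron_id] = pos
    df = pd.DataFrame(rows)
    df["group"] = [
        f"{s}_{a}" if s else "ungrouped"
        for s, a in zip(df["strain"], df["age"])
    ]
    if len(df) < 2:
        logger.warning("single-neuron cohort: group statistics skipped")
        stats = {"groups": {}, "comparisons": {}}
    else:
        stats = _group_stats(df, positions, cfg)
    stats["config_hash"] = cfg.config_hash()
    stats["rng_seed"] = cfg.rng_seed
    stats["version"] = __version__
    stats["n_neurons"] = int(len(df))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "summary.csv", index=False)
        with open(out_dir / "stats.json", "w") as fh:
            json.dump(stats, fh, indent=2, sort_keys=True)
        # event positions (µm from the distal tip), consumable by the
        # `associate` CLI verb
        ev_rows = []
        for nid in df["neuron_id"]:
            if nid not in positions:
                continue
            ep = positions[nid]
            for kind, arr in (
                ("bend", ep.bend_positions),
                ("outgrowth", ep.outgrowth_positions),
            ):
                for p in arr:
                    ev_rows.append(
                        {
                            "neuron_id": nid,
                            "event_type": kind,
                            "position_um": float(p),
                            "main_length_um": ep.main_length,
                        }
                    )
        pd.DataFrame(
            ev_rows,
            columns=["neuron_id", "event_type", "position_um",
                     "main_length_um"],
        ).to_csv(out_dir / "events.csv", index=False)
    return df, stats


def sweep_cohort(
    input_dir: str | Path,
    cfg: RunConfig | None = None,
    thresholds=(135.0, 140.0, 145.0, 150.0, 155.0, 160.0, 165.0),
) -> pd.DataFrame:
    """Bend density per angle threshold for every neuron in a directory."""
    cfg = cfg or RunConfig()
    rows = []
    for swc in sorted(Path(input_dir).glob("*.swc")):
        meta = parse_neuron_name(str(swc))
        ncls = meta["neuron_class"]
        if not ncls:
            continue
        tree = read_swc(swc, unit_scale=cfg.unit_scale)
        ct = classify_alm(tree, cfg.classify) if ncls == "ALM" else classify_plm(
            tree, cfg.classify
        )
        dens = threshold_sweep(
            MainBranchGeometry.from_classified(ct), cfg.morph, thresholds
        )
        for t, d in dens.items():
            rows.append(
                {"neuron_id": swc.stem, "threshold_deg": t, "bend_density": d}
            )
    return pd.DataFrame(rows)
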