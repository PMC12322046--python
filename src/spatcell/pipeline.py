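"""End-to-end orchestration: QCM → cross-PCF → NCF → ACN/CCN → network.

The pipeline mirrors the sequential screening logic of the analysis: the
quadrat correlation matrix gates cell-type pairs into cross-PCF analysis;
pooled g(r = 20) values rank pairs, feed the NCF triplet choice and the
final network filter; contact analysis runs on the label masks. Every
stage writes tidy CSV output and the run closes with a JSON manifest
recording versions, seeds, parameters and per-stage pair/triplet counts.
All randomness derives deterministically from one master seed, so a rerun
with identical config and inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .abundance import densities
from .contact import build_acn, ccn_condition, ccn_edges, assemble_network
from .data import CellPattern, read_cell_table, read_label_mask
from .ncf import NCFParams, ncf, ncf_condition
from .pcf import PCFParams, cross_pcf, pool_pcf, tcm
from .qcm import qcm_screen

__all__ = ["RunConfig", "derive_seed", "count_candidate_pairs", "run_pipeline"]

logger = logging.getLogger("spatcell")


def derive_seed(master_seed: int, *parts) -> int:
    """Stable sub-seed (< 2³¹) from the master seed and a context key.

    Hash-derived per (module, condition, roi, pair) so stages are
    reproducible independently of execution order.
    """
    h = hashlib.blake2s(repr((int(master_seed),) + tuple(map(str, parts))).encode())
    return int.from_bytes(h.digest()[:4], "little") % (2**31)


def count_candidate_pairs(n_types: int, n_conditions: int) -> int:
    """Ordered cell-type pairs (self-pairs included) per condition, summed."""
    if n_types < 1 or n_conditions < 1:
        raise ValueError("need n_types >= 1 and n_conditions >= 1")
    return n_types * n_types * n_conditions


@dataclass
class RunConfig:
    """All pipeline inputs and parameters; defaults follow the reference protocol."""

    cell_table: str | None = None
    masks: dict = field(default_factory=dict)  # roi_id -> mask path
    schema: dict = field(default_factory=dict)
    window: tuple | None = None  # (width, height) µm, applied to all ROIs
    pixel_size: float = 1.0
    types_for_spatial: list | None = None

    quadrat_size: float = 100.0
    qcm_shuffles: int = 1000
    qcm_alpha: float = 0.05

    pcf_inner_radius: float = 20.0
    pcf_annulus_width: float = 10.0
    pcf_max_radius: float = 300.0
    pcf_step: float = 5.0
    pcf_n_boot: int = 1000

    tcm_threshold: float = 100.0
    tcm_pairs: list = field(default_factory=list)  # [(type_a, type_b), ...]

    ncf_triplets: list = field(default_factory=list)  # [(c1, c2, c3), ...]
    ncf_bin_width: float = 5.0
    ncf_max_radius: float = 150.0
    ncf_M: int = 10_000_000
    ncf_n_boot: int = 1000
    ncf_subsample_cap: int = 5_000_000
    ncf_shuffle_universe: str = "triplet_types"

    contact_rule: str = "chebyshev1"
    ccn_permutations: int = 1000
    ccn_alpha: float = 0.05

    seed: int = 0
    outdir: str = "spatcell_out"
    write_graphml: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.window is not None:
            cfg.window = tuple(cfg.window)
        cfg.tcm_pairs = [tuple(p) for p in cfg.tcm_pairs]
        cfg.ncf_triplets = [tuple(t) for t in cfg.ncf_triplets]
        return cfg

    def params_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]

    def pcf_params(self, seed: int) -> PCFParams:
        return PCFParams(
            inner_radius=self.pcf_inner_radius,
            annulus_width=self.pcf_annulus_width,
            curve_radii=tuple(np.arange(0.0, self.pcf_max_radius + self.pcf_step / 2, self.pcf_step)),
            n_boot=self.pcf_n_boot,
            seed=seed,
        )

    def ncf_params(self, seed: int) -> NCFParams:
        return NCFParams(
            bin_width=self.ncf_bin_width,
            max_radius=self.ncf_max_radius,
            M=self.ncf_M,
            n_boot=self.ncf_n_boot,
            seed=seed,
            subsample_cap=self.ncf_subsample_cap,
            shuffle_universe=self.ncf_shuffle_universe,
        )


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def _derive_triplets(pooled_g20: dict, condition_pairs: dict) -> list:
    """One triplet per condition from the top pooled-g20 passing pairs.

    Distinct types are collected in descending pooled-g20 rank until three
    accumulate; conditions with fewer than three distinct passing types
    contribute none.
    """
    triplets = set()
    for cond, pairs in condition_pairs.items():
        ranked = sorted(
            (p for p in pairs if (cond, p) in pooled_g20 and np.isfinite(pooled_g20[(cond, p)])),
            key=lambda p: -pooled_g20[(cond, p)],
        )
        seen: list = []
        for a, b in ranked:
            for t in (a, b):
                if t not in seen:
                    seen.append(t)
            if len(seen) >= 3:
                break
        if len(seen) >= 3:
            triplets.add(tuple(seen[:3]))
    return sorted(triplets)


def run_pipeline(
    config: RunConfig,
    patterns: list[CellPattern] | None = None,
    masks: dict | None = None,
) -> dict:
    """Execute the five analysis stages and return the run manifest.

    Inputs may be given in-memory (``patterns``, ``masks`` keyed by roi_id)
    or through ``config.cell_table`` / ``config.masks`` paths. A stage
    failure is recorded in the manifest and later stages that depend on it
    are skipped; outputs already written are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if patterns is None:
        if config.cell_table is None:
            raise ValueError("no input: provide patterns or config.cell_table")
        schema = dict(config.schema)
        if config.window is not None:
            schema["window"] = tuple(config.window)
        patterns = read_cell_table(config.cell_table, schema=schema)
    if masks is None:
        masks = {
            roi: read_label_mask(path, pixel_size=config.pixel_size)
            for roi, path in sorted(config.masks.items())
        }
    patterns = sorted(patterns, key=lambda p: (p.condition, p.roi_id))
    types = config.types_for_spatial or sorted({t for p in patterns for t in p.types})
    conditions = sorted({p.condition for p in patterns})
    by_condition = {c: [p for p in patterns if p.condition == c] for c in conditions}

    manifest = {
        "package": "spatcell",
        "version": __version__,
        "seed": config.seed,
        "params_hash": config.params_hash(),
        "n_rois": len(patterns),
        "n_types": len(types),
        "candidate_pairs": count_candidate_pairs(len(types), len(conditions)),
        "stages": {},
    }

    dens_table = densities(patterns, types=types)
    _write_csv(dens_table, outdir / "densities.csv")

    # ---- stage 1: QCM ------------------------------------------------------
    condition_pairs: dict = {}
    try:
        qcm_frames = []
        for p in patterns:
            res = qcm_screen(
                p,
                quadrat_size=config.quadrat_size,
                n_shuffles=config.qcm_shuffles,
                seed=derive_seed(config.seed, "qcm", p.condition, p.roi_id),
                pass_alpha=config.qcm_alpha,
                types=[t for t in types if t in p.types] or None,
            )
            qcm_frames.append(res.to_frame())
        qcm_table = pd.concat(qcm_frames, ignore_index=True)
        _write_csv(qcm_table, outdir / "qcm.csv")
        for cond in conditions:
            sub = qcm_table[(qcm_table["condition"] == cond) & qcm_table["pass"]]
            condition_pairs[cond] = sorted(
                {tuple(x) for x in sub[["type_a", "type_b"]].itertuples(index=False)}
            )
        n_pass = sum(len(v) for v in condition_pairs.values())
        manifest["stages"]["qcm"] = {"status": "ok", "passing_pairs": n_pass}
        logger.info("QCM: %d unordered pairs pass across %d conditions", n_pass, len(conditions))
    except Exception as exc:  # pragma: no cover - defensive
        manifest["stages"]["qcm"] = {"status": "failed", "error": str(exc)}
        condition_pairs = {}

    # ---- stage 2: cross-PCF (QCM-passing pairs, both orientations) ---------
    pooled_g20: dict = {}
    try:
        pcf_frames = []
        g20_rows = []
        n_pairs_run = 0
        for cond in conditions:
            ordered = sorted(
                {(a, b) for (x, y) in condition_pairs.get(cond, []) for (a, b) in ((x, y), (y, x))}
            )
            for a, b in ordered:
                per_roi = []
                for p in by_condition[cond]:
                    params = config.pcf_params(
                        derive_seed(config.seed, "pcf", cond, p.roi_id, a, b)
                    )
                    res = cross_pcf(p, a, b, params)
                    per_roi.append(res)
                    pcf_frames.append(res.to_frame())
                defined = [r for r in per_roi if r.defined]
                if defined:
                    pooled = pool_pcf(defined)
                    pcf_frames.append(pooled.to_frame())
                    g20 = pooled.at(config.pcf_inner_radius)
                    pooled_g20[(cond, (a, b))] = g20
                    g20_rows.append(
                        {"condition": cond, "type_a": a, "type_b": b, "g20": g20,
                         "g_max": pooled.g_max, "r_at_g_max": pooled.r_at_g_max}
                    )
                n_pairs_run += 1
        if pcf_frames:
            _write_csv(pd.concat(pcf_frames, ignore_index=True), outdir / "pcf_curves.csv")
        _write_csv(pd.DataFrame(g20_rows), outdir / "g20.csv")
        manifest["stages"]["pcf"] = {"status": "ok", "ordered_pairs": n_pairs_run}
        logger.info("cross-PCF: %d ordered pairs evaluated", n_pairs_run)
    except Exception as exc:  # pragma: no cover - defensive
        manifest["stages"]["pcf"] = {"status": "failed", "error": str(exc)}

    # optional TCM output for explicitly requested pairs
    if config.tcm_pairs:
        tcm_frames = []
        for cond in conditions:
            for a, b in config.tcm_pairs:
                for p in by_condition[cond]:
                    if a not in p.types:
                        continue
                    fld = tcm(p, a, b, threshold=config.tcm_threshold)
                    tcm_frames.append(fld.to_frame())
                    tifffile.imwrite(
                        outdir / f"tcm_{cond}_{p.roi_id}_{a}_{b}.tiff",
                        fld.grid.astype(np.float32),
                    )
        if tcm_frames:
            _write_csv(pd.concat(tcm_frames, ignore_index=True), outdir / "tcm_cells.csv")

    # ---- stage 3: NCF ------------------------------------------------------
    try:
        triplets = [tuple(t) for t in config.ncf_triplets] or _derive_triplets(
            pooled_g20, condition_pairs
        )
        ncf_frames = []
        for cond in conditions:
            for trip in triplets:
                per_roi = []
                for p in by_condition[cond]:
                    params = config.ncf_params(
                        derive_seed(config.seed, "ncf", cond, p.roi_id, *trip)
                    )
                    res = ncf(p, *trip, params=params)
                    per_roi.append(res)
                    ncf_frames.append(res.to_frame())
                defined = [r for r in per_roi if r.defined]
                if defined:
                    ncf_frames.append(ncf_condition(defined).to_frame())
        if ncf_frames:
            _write_csv(pd.concat(ncf_frames, ignore_index=True), outdir / "ncf.csv")
        manifest["stages"]["ncf"] = {"status": "ok", "triplets": len(triplets)}
        logger.info("NCF: %d triplets evaluated", len(triplets))
    except Exception as exc:  # pragma: no cover - defensive
        manifest["stages"]["ncf"] = {"status": "failed", "error": str(exc)}

    # ---- stage 4: ACN / CCN ------------------------------------------------
    ccn_cond_table = None
    try:
        if masks:
            roi_frames = []
            for p in patterns:
                if p.roi_id not in masks:
                    continue
                graph = build_acn(masks[p.roi_id], p, contact_rule=config.contact_rule)
                roi_frames.append(
                    ccn_edges(
                        graph,
                        p,
                        n_perm=config.ccn_permutations,
                        seed=derive_seed(config.seed, "ccn", p.condition, p.roi_id),
                    )
                )
            roi_table = pd.concat(roi_frames, ignore_index=True)
            _write_csv(roi_table, outdir / "ccn_roi.csv")
            ccn_cond_table = ccn_condition(roi_table)
            _write_csv(ccn_cond_table, outdir / "ccn_condition.csv")
            manifest["stages"]["ccn"] = {
                "status": "ok",
                "rois": len(roi_frames),
                "pairs": int(len(ccn_cond_table)),
            }
        else:
            manifest["stages"]["ccn"] = {"status": "skipped", "reason": "no masks provided"}
    except Exception as exc:  # pragma: no cover - defensive
        manifest["stages"]["ccn"] = {"status": "failed", "error": str(exc)}

    # ---- stage 5: network assembly -----------------------------------------
    try:
        if ccn_cond_table is not None and len(pooled_g20):
            net_frames = []
            mean_density = (
                dens_table.groupby("cell_type")["density"].mean().to_dict()
            )
            for cond in conditions:
                sub = ccn_cond_table[ccn_cond_table["condition"] == cond]
                g20_map = {pair: g for (c, pair), g in pooled_g20.items() if c == cond}
                if not len(sub) or not g20_map:
                    continue
                sub = sub[
                    sub.apply(lambda r: (r["type_a"], r["type_b"]) in g20_map, axis=1)
                ]
                if not len(sub):
                    continue
                G, edges, communities = assemble_network(
                    sub, g20_map, alpha=config.ccn_alpha, densities=mean_density
                )
                net_frames.append(edges)
                if config.write_graphml and G.number_of_edges():
                    import networkx as nx

                    nx.write_graphml(G, outdir / f"network_{cond}.graphml")
            if net_frames:
                _write_csv(pd.concat(net_frames, ignore_index=True), outdir / "network_edges.csv")
                n_kept = int(pd.concat(net_frames)["keep"].sum())
            else:
                n_kept = 0
            manifest["stages"]["network"] = {"status": "ok", "kept_edges": n_kept}
        else:
            manifest["stages"]["network"] = {
                "status": "skipped",
                "reason": "requires CCN results and pooled g(20)",
            }
    except Exception as exc:  # pragma: no cover - defensive
        manifest["stages"]["network"] = {"status": "failed", "error": str(exc)}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
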