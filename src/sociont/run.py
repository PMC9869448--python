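"""Run orchestration: single runs, replicate sweeps, manifests and outputs.

Outputs per run: an incrementally flushed metrics CSV, a JSONL log of split
events, a YAML manifest (config, seed, config hash, code version), a final
snapshot (owner raster + agent/community tables) and Newick exports of the
live institution trees.  Identical (config, seed) pairs produce
byte-identical metrics streams.
"""

from __future__ import annotations

import csv
import datetime
import hashlib
import json
import pathlib
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, metrics
from .config import SimConfig, config_to_dict, override
from .world import World, seed_world, step

__all__ = ["run", "sweep", "config_hash", "export_snapshot",
           "export_newick"]


def config_hash(cfg: SimConfig) -> str:
    blob = yaml.safe_dump(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _flush_rows(writer_state: dict, rows: list[dict], fh) -> None:
    for row in rows:
        if writer_state.get("writer") is None:
            writer_state["fields"] = list(row)
            writer_state["writer"] = csv.DictWriter(fh, writer_state["fields"])
            writer_state["writer"].writeheader()
        writer_state["writer"].writerow(
            {k: row.get(k, "") for k in writer_state["fields"]})
    if rows:
        fh.flush()


def run(cfg: SimConfig, seed: int, out_dir: str | pathlib.Path,
        updates: int, label: str = "run",
        snapshot: bool = True) -> dict[str, Any]:
    """Execute ``updates`` model updates and write all outputs.

    Refuses to overwrite an existing manifest for the same label.
    Returns the manifest mapping.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / f"{label}.manifest.yaml"
    if manifest_path.exists():
        raise FileExistsError(
            f"manifest {manifest_path} already exists; refusing to overwrite")
    started = datetime.datetime.now().isoformat(timespec="seconds")

    rng = np.random.default_rng(seed)
    world = seed_world(cfg, rng)
    metrics_path = out / f"{label}.metrics.csv"
    splits_path = out / f"{label}.splits.jsonl"
    writer_state: dict = {"writer": None}
    n_rows = 0
    n_splits = 0
    with metrics_path.open("w", newline="") as mfh, \
            splits_path.open("w") as sfh:
        for _ in range(updates):
            step(world)
            if len(world.metrics_rows) > n_rows:
                _flush_rows(writer_state, world.metrics_rows[n_rows:], mfh)
                n_rows = len(world.metrics_rows)
            if len(world.split_events) > n_splits:
                for ev in world.split_events[n_splits:]:
                    sfh.write(json.dumps(
                        {"update": ev.update, "parent": ev.parent,
                         "parent_class": ev.parent_class,
                         "daughters": list(ev.daughters),
                         "daughter_classes": list(ev.daughter_classes)}) + "\n")
                sfh.flush()
                n_splits = len(world.split_events)

    files = {"metrics": metrics_path.name, "splits": splits_path.name}
    if snapshot:
        files.update(export_snapshot(world, out, label))
    manifest = {
        "label": label,
        "scenario_hash": config_hash(cfg),
        "seed": int(seed),
        "updates": int(updates),
        "version": __version__,
        "config": config_to_dict(cfg),
        "outputs": files,
        "started": started,
        "finished": datetime.datetime.now().isoformat(timespec="seconds"),
        "final_population": world.population,
        "final_communities": len(world.communities),
    }
    with manifest_path.open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def export_snapshot(world: World, out: pathlib.Path,
                    label: str) -> dict[str, str]:
    """Owner raster (npz + plain PGM), agent/community CSV tables and
    Newick institution trees."""
    files: dict[str, str] = {}
    npz = out / f"{label}.snapshot.npz"
    np.savez_compressed(npz, owner=world.owner, t=world.t)
    files["snapshot"] = npz.name

    from .render import save_pgm
    pgm = out / f"{label}.owners.pgm"
    save_pgm(world.owner, pgm)
    files["raster"] = pgm.name

    agents = []
    coms = []
    for com in world.sorted_communities():
        coms.append({"community": com.id, "parent": com.parent_id,
                     "birth_update": com.birth_time, "members": com.n,
                     "territory_cells": com.territory_size,
                     "class": metrics.complexity_class(com, world).cls})
        for i in range(com.n):
            agents.append({"community": com.id, "age": float(com.age[i]),
                           "energy": float(com.energy[i]),
                           "buffer": float(com.buffer[i]),
                           "rank_score": float(com.rank_score[i]),
                           "capacity": float(com.capacity[i]),
                           "n_alleles": int(com.alleles_view[i].sum())})
    pd.DataFrame(coms).to_csv(out / f"{label}.communities.csv", index=False)
    pd.DataFrame(agents).to_csv(out / f"{label}.agents.csv", index=False)
    files["communities"] = f"{label}.communities.csv"
    files["agents"] = f"{label}.agents.csv"

    nwk = out / f"{label}.institutions.nwk"
    export_newick(world, nwk)
    files["institutions"] = nwk.name
    return files


def export_newick(world: World, path: pathlib.Path) -> None:
    """One Newick tree per apex locus, labelled by locus ids."""
    import dendropy

    trees = dendropy.TreeList()
    registry = world.registry
    for apex in registry.apex_slots:
        taxa = trees.taxon_namespace
        tree = dendropy.Tree(taxon_namespace=taxa)
        nodes = {apex: tree.seed_node}
        tree.seed_node.label = f"L{registry.loci[apex].id}"
        for slot in registry.tree_components(apex):
            node = dendropy.Node(label=f"L{registry.loci[slot].id}")
            nodes[int(registry.parent[slot])].add_child(node)
            nodes[slot] = node
        trees.append(tree)
    trees.write(path=str(path), schema="newick",
                suppress_rooting=True, suppress_edge_lengths=True)


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Stable derived seeds for replicate batches."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31 - 1))
            for child in ss.spawn(n)]


def sweep(cfg: SimConfig, parameter: str, values: Sequence[float],
          replicates: int, out_dir: str | pathlib.Path, updates: int,
          seed: int, label: str = "sweep") -> dict[str, Any]:
    """Run ``values x replicates`` runs and aggregate glass-ceiling
    estimates.  An invalid parameter name errors before any run starts;
    individual run failures are recorded and the sweep continues.
    """
    override(cfg, **{parameter: values[0]})  # validates the key up front
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = spawn_seeds(seed, len(values) * replicates)
    entries = []
    rows = []
    i = 0
    for v in values:
        for rep in range(replicates):
            run_label = f"{label}_{parameter}{v}_r{rep}"
            child_seed = seeds[i]
            i += 1
            entry = {"label": run_label, "value": v, "replicate": rep,
                     "seed": child_seed}
            try:
                cfg_v = override(cfg, **{parameter: v})
                run(cfg_v, child_seed, out, updates, label=run_label,
                    snapshot=False)
                df = pd.read_csv(out / f"{run_label}.metrics.csv")
                gc = metrics.glass_ceiling(df["mean_class"].to_numpy())
                entry.update(status="ok", ceiling=gc.estimate,
                             converged=gc.converged)
                rows.append({"value": v, "replicate": rep,
                             "ceiling": gc.estimate,
                             "converged": gc.converged})
            except Exception as exc:   # noqa: BLE001 - sweep must continue
                entry.update(status="error", error=str(exc))
            entries.append(entry)
    table = pd.DataFrame(rows)
    agg = (table.groupby("value")["ceiling"].agg(["mean", "std", "count"])
           .reset_index()) if len(table) else pd.DataFrame()
    table.to_csv(out / f"{label}.runs.csv", index=False)
    agg.to_csv(out / f"{label}.table.csv", index=False)
    manifest = {"label": label, "parameter": parameter,
                "values": [float(v) for v in values],
                "replicates": replicates, "seed": int(seed),
                "entries": entries,
                "outputs": {"runs": f"{label}.runs.csv",
                            "table": f"{label}.table.csv"}}
    with (out / f"{label}.manifest.yaml").open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
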