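"""Result persistence: trajectories/ensembles in HDF5, fits as JSON."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .network import build_lac_network
from .ssa import Ensemble, Trajectory


def save_ensemble(path: str | Path, ensemble: Ensemble) -> None:
    with h5py.File(path, "w") as f:
        net = f.create_group("network")
        net.attrs["variant"] = ensemble.network.variant
        net.attrs["inducer_kind"] = ensemble.network.inducer_kind
        net.attrs["volume"] = ensemble.network.volume
        net.attrs["species"] = json.dumps(ensemble.network.species)
        cond = f.create_group("condition")
        for k, v in ensemble.condition.items():
            cond.attrs[k] = v
        if ensemble.seeds is not None:
            f.create_dataset("seeds", data=ensemble.seeds)
        cells = f.create_group("cells")
        for i, tr in enumerate(ensemble.trajectories):
            g = cells.create_group(str(i))
            g.create_dataset("times", data=tr.times)
            g.create_dataset("counts", data=tr.counts,
                             compression="gzip", compression_opts=4)
            if tr.event_times is not None:
                g.create_dataset("event_times", data=tr.event_times)
                g.create_dataset("event_reactions", data=tr.event_reactions)


def load_ensemble(path: str | Path) -> Ensemble:
    with h5py.File(path, "r") as f:
        net_attrs = f["network"].attrs
        network = build_lac_network(net_attrs["variant"],
                                    net_attrs["inducer_kind"])
        species = json.loads(net_attrs["species"])
        condition = dict(f["condition"].attrs)
        seeds = f["seeds"][...] if "seeds" in f else None
        trajectories = []
        for key in sorted(f["cells"], key=int):
            g = f["cells"][key]
            trajectories.append(Trajectory(
                times=g["times"][...], counts=g["counts"][...],
                species=species, network=network,
                event_times=(g["event_times"][...]
                             if "event_times" in g else None),
                event_reactions=(g["event_reactions"][...]
                                 if "event_reactions" in g else None)))
    return Ensemble(trajectories=trajectories, network=network,
                    condition=condition, seeds=seeds)


def save_fit(path: str | Path, fit) -> None:
    with open(path, "w") as fh:
        json.dump(fit.to_record(), fh, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not serializable: {type(obj)}")


def write_manifest(out_dir: str | Path, config: dict) -> Path:
    """Write a run manifest (configuration, seeds, package version)."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"package": "lacswitch", "version": __version__,
                "config": config}
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonify)
    return path
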