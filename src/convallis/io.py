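"""HDF5 serialization of recordings, ensembles and networks, plus the
adapter for user-supplied intensity matrices."""

from __future__ import annotations

import json

import h5py
import numpy as np

from . import __version__
from .core_sim import Network, NeuronParams, SpikeTrainSet, SynapseGroup
from .stimuli import IntensityEnsemble, SyntheticDigitSpec, Utterance

__all__ = [
    "save_recording",
    "load_recording",
    "save_ensemble",
    "load_ensemble",
    "save_network",
    "load_network",
]


def _write_meta(f, meta: dict | None, seed=None):
    g = f.require_group("meta")
    g.attrs["version"] = __version__
    if seed is not None:
        g.attrs["seed"] = seed
    if meta:
        g.attrs["json"] = json.dumps(meta, default=str)


def save_recording(path, spikes: dict, voltage: dict | None = None,
                   meta: dict | None = None, seed=None, dt: float = 0.1):
    """Write spike trains (``/spikes/<pop>`` as (neuron, time ms) pairs) and
    optional dt-sampled voltage traces (``/voltage/<id>``)."""
    with h5py.File(path, "w") as f:
        for pop, trains in spikes.items():
            tr = trains.trains if isinstance(trains, SpikeTrainSet) else trains
            ids = np.concatenate(
                [np.full(len(t), i) for i, t in enumerate(tr)]
            ) if tr else np.empty(0)
            times = np.concatenate(tr) if tr else np.empty(0)
            f.create_dataset(f"spikes/{pop}", data=np.stack([ids, times], axis=1))
            f[f"spikes/{pop}"].attrs["n_neurons"] = len(tr)
        if voltage:
            for nid, trace in voltage.items():
                d = f.create_dataset(f"voltage/{nid}", data=np.asarray(trace))
                d.attrs["dt"] = dt
        _write_meta(f, meta, seed)


def load_recording(path):
    spikes, voltage, meta = {}, {}, {}
    with h5py.File(path, "r") as f:
        for pop in f.get("spikes", {}):
            data = f[f"spikes/{pop}"][...]
            n = int(f[f"spikes/{pop}"].attrs["n_neurons"])
            trains = [np.sort(data[data[:, 0] == i, 1]) for i in range(n)]
            spikes[pop] = SpikeTrainSet(trains)
        for nid in f.get("voltage", {}):
            voltage[nid] = f[f"voltage/{nid}"][...]
        if "meta" in f and "json" in f["meta"].attrs:
            meta = json.loads(f["meta"].attrs["json"])
    return spikes, voltage, meta


def save_ensemble(path, ens: IntensityEnsemble, meta=None):
    with h5py.File(path, "w") as f:
        labels, speakers = [], []
        for k, u in enumerate(ens.utterances):
            f.create_dataset(f"utterances/{k}/intensity", data=u.intensity)
            labels.append(u.label)
            speakers.append(u.speaker)
        f.create_dataset("labels", data=np.array(labels))
        f.create_dataset("speakers", data=np.array(speakers))
        f.attrs["spec"] = json.dumps(ens.spec.__dict__)
        _write_meta(f, meta)


def load_ensemble(path) -> IntensityEnsemble:
    """Read an intensity ensemble; also the documented container format for
    user-supplied (e.g. real cochleogram) matrices."""
    with h5py.File(path, "r") as f:
        labels = f["labels"][...]
        speakers = f["speakers"][...]
        utterances = [
            Utterance(
                intensity=f[f"utterances/{k}/intensity"][...],
                label=int(labels[k]),
                speaker=int(speakers[k]),
            )
            for k in range(len(labels))
        ]
        spec = SyntheticDigitSpec(**json.loads(f.attrs["spec"])) \
            if "spec" in f.attrs else None
    return IntensityEnsemble(utterances=utterances, spec=spec)


def save_network(path, net: Network, meta=None):
    with h5py.File(path, "w") as f:
        f.attrs["n_neurons"] = net.n_neurons
        f.attrs["n_inputs"] = net.n_inputs
        f.attrs["background_rate"] = net.background_rate
        f.attrs["background_weight"] = net.background_weight
        f.attrs["params"] = json.dumps(net.params.__dict__)
        if net.positions is not None:
            f.create_dataset("positions", data=net.positions)
        for k, g in enumerate(net.groups):
            grp = f.create_group(f"groups/{k}")
            for name in ("source_ids", "target_ids", "weights", "delays"):
                grp.create_dataset(name, data=getattr(g, name))
            grp.attrs["reversal_class"] = g.reversal_class
            grp.attrs["plastic"] = g.plastic
            grp.attrs["source_kind"] = g.source_kind
            grp.attrs["name"] = g.name
        _write_meta(f, meta)


def load_network(path) -> Network:
    with h5py.File(path, "r") as f:
        net = Network(
            n_neurons=int(f.attrs["n_neurons"]),
            n_inputs=int(f.attrs["n_inputs"]),
            params=NeuronParams(**json.loads(f.attrs["params"])),
            background_rate=float(f.attrs["background_rate"]),
            background_weight=float(f.attrs["background_weight"]),
            positions=f["positions"][...] if "positions" in f else None,
        )
        ks = sorted((f["groups"] if "groups" in f else {}), key=int)
        for k in ks:
            grp = f[f"groups/{k}"]
            net.add_group(SynapseGroup(
                source_ids=grp["source_ids"][...],
                target_ids=grp["target_ids"][...],
                weights=grp["weights"][...],
                delays=grp["delays"][...],
                reversal_class=grp.attrs["reversal_class"],
                plastic=bool(grp.attrs["plastic"]),
                source_kind=grp.attrs["source_kind"],
                name=grp.attrs["name"],
            ))
    return net
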