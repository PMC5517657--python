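"""Volume, registry and configuration IO with provenance.

Volumes round-trip losslessly through multi-page TIFF stacks and HDF5
datasets; both carry the voxel size (µm) and an optional provenance mapping
as metadata.  The vessel registry serializes to JSON/GraphML and the phantom
spec / disease model to YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import h5py
import networkx as nx
import numpy as np
import tifffile
import yaml

from . import phantom as ph


def write_volume(path, data: np.ndarray, voxel_size_um: float,
                 provenance: Optional[dict] = None) -> None:
    """Write a 3D volume as .tif/.tiff stack or .h5/.hdf5 dataset."""
    path = Path(path)
    meta = {"voxel_size_um": float(voxel_size_um)}
    if provenance:
        meta["provenance"] = provenance
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(data), metadata=meta)
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("volume", data=np.asarray(data))
            ds.attrs["voxel_size_um"] = float(voxel_size_um)
            if provenance:
                ds.attrs["provenance"] = json.dumps(provenance, sort_keys=True)
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r}")


def read_volume(path, voxel_size_um: Optional[float] = None
                ) -> tuple[np.ndarray, float]:
    """Read a volume; the voxel size must be stored or passed explicitly."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        vs = meta.get("voxel_size_um", voxel_size_um)
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            ds = f["volume"]
            data = ds[()]
            vs = ds.attrs.get("voxel_size_um", voxel_size_um)
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r}")
    if vs is None:
        raise ValueError(f"{path} carries no voxel size; pass voxel_size_um explicitly")
    return data, float(vs)


def write_phantom_h5(path, phantom: ph.LabeledVolume, delta: Optional[np.ndarray] = None,
                     beta: Optional[np.ndarray] = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=phantom.labels, compression=None)
        if delta is not None:
            f.create_dataset("delta", data=delta)
        if beta is not None:
            f.create_dataset("beta", data=beta)
        f.attrs["voxel_size_um"] = phantom.voxel_size_um
        f.attrs["mode"] = phantom.mode
        f.attrs["registry"] = registry_json(phantom)


def registry_json(phantom: ph.LabeledVolume) -> str:
    g = phantom.vessel_graph
    reg = {
        "nodes": [{"id": int(n), "pos_um": list(map(float, d["pos"])),
                   "kind": d["kind"]} for n, d in g.nodes(data=True)],
        "edges": [{"u": int(u), "v": int(v), "diameter_um": float(d["diameter_um"]),
                   "length_um": float(d["length_um"]), "kind": d["kind"]}
                  for u, v, d in g.edges(data=True)],
        "neurons": [{"centroid_um": list(map(float, n["centroid_um"])),
                     "diameter_um": float(n["diameter_um"])} for n in phantom.neurons],
        "occlusions": [{"arc_um": o["arc_um"],
                        "center_um": list(map(float, o["center_um"])),
                        "diameter_um": float(o["diameter_um"])}
                       for o in phantom.occlusions],
        "branch_count": phantom.branch_count,
        "neuron_count": phantom.neuron_count,
    }
    return json.dumps(reg, sort_keys=True)


def write_graphml(path, graph: nx.Graph) -> None:
    g = nx.Graph()
    for n, d in graph.nodes(data=True):
        attrs = {k: (",".join(f"{x:.3f}" for x in v) if isinstance(v, np.ndarray) else v)
                 for k, v in d.items()}
        g.add_node(n, **attrs)
    for u, v, d in graph.edges(data=True):
        attrs = {k: val for k, val in d.items()
                 if isinstance(val, (int, float, str, bool))}
        g.add_edge(u, v, **attrs)
    nx.write_graphml(g, path)


# --------------------------------------------------------------------------
# YAML config helpers
# --------------------------------------------------------------------------

def _asdict(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _asdict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_asdict(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def spec_to_yaml(spec: ph.PhantomSpec, disease: ph.DiseaseModel, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump({"phantom": _asdict(spec), "disease": _asdict(disease)}, f,
                       sort_keys=True)


def spec_from_yaml(path) -> tuple[ph.PhantomSpec, ph.DiseaseModel]:
    with open(path) as f:
        doc = yaml.safe_load(f)
    return phantom_spec_from_dict(doc["phantom"]), disease_from_dict(doc.get("disease", {}))


def phantom_spec_from_dict(d: dict) -> ph.PhantomSpec:
    d = dict(d)
    for key, cls in (("butterfly", ph.ButterflyParams), ("vessels", ph.VesselTreeParams),
                     ("neurons", ph.NeuronParams), ("capillaries", ph.CapillaryParams)):
        if key in d and isinstance(d[key], dict):
            d[key] = cls(**{k: _tup(v) for k, v in d[key].items()})
    if "shape" in d:
        d["shape"] = tuple(d["shape"])
    return ph.PhantomSpec(**d)


def disease_from_dict(d: dict) -> ph.DiseaseModel:
    return ph.DiseaseModel(**d)


def _tup(v):
    return tuple(v) if isinstance(v, list) else v


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    payload = json.dumps(_asdict(obj), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
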