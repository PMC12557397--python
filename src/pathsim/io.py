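"""Delimited-text serialization of matrices, profiles and work tables.

Square distance/similarity matrices go to CSV with the trajectory ids as
header row and first column, preceded by ``#``-prefixed provenance lines
(measure, preprocessing fingerprint, config hash).  Free-energy profiles
and work ensembles are TSV.  HDF5 matrix storage mirrors the CSV content in
a dataset with attributes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dctmd import FreeEnergyProfile, WorkEnsemble
from .measures import DistanceMatrix, SimilarityMatrix

__all__ = [
    "write_matrix", "read_distance_matrix", "read_similarity_matrix",
    "write_profile", "read_profile",
    "write_work_ensemble", "read_work_ensemble",
]


def write_matrix(m: DistanceMatrix | SimilarityMatrix, path: str,
                 extra_meta: dict[str, str] | None = None) -> None:
    kind = "similarity" if isinstance(m, SimilarityMatrix) else "distance"
    with open(path, "w") as f:
        f.write(f"# kind\t{kind}\n")
        f.write(f"# measure\t{m.measure}\n")
        f.write(f"# preprocessing\t{m.preprocessing}\n")
        for k, v in (extra_meta or {}).items():
            f.write(f"# {k}\t{v}\n")
        pd.DataFrame(m.values, index=m.traj_ids, columns=m.traj_ids).to_csv(f)


def _read_matrix(path: str) -> tuple[np.ndarray, list[str], dict[str, str]]:
    meta: dict[str, str] = {}
    with open(path) as f:
        pos = f.tell()
        line = f.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("\t")
            meta[key.strip()] = value
            pos = f.tell()
            line = f.readline()
        f.seek(pos)
        df = pd.read_csv(f, index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns], meta


def read_distance_matrix(path: str) -> DistanceMatrix:
    values, ids, meta = _read_matrix(path)
    return DistanceMatrix(values, measure=meta.get("measure", "unknown"),
                          preprocessing=meta.get("preprocessing", "raw"), traj_ids=ids)


def read_similarity_matrix(path: str) -> SimilarityMatrix:
    values, ids, meta = _read_matrix(path)
    return SimilarityMatrix(values, measure=meta.get("measure", "unknown"),
                            preprocessing=meta.get("preprocessing", "raw"), traj_ids=ids)


def write_profile(profile: FreeEnergyProfile, path: str,
                  extra_meta: dict[str, str] | None = None) -> None:
    with open(path, "w") as f:
        f.write(f"# n_used\t{profile.n_used}\n")
        for k, v in (extra_meta or {}).items():
            f.write(f"# {k}\t{v}\n")
        f.write("x\tdeltaG\tmean_work\tw_diss\n")
        np.savetxt(f, profile.to_table(), delimiter="\t", fmt="%.10g")


def read_profile(path: str) -> FreeEnergyProfile:
    meta: dict[str, str] = {}
    with open(path) as f:
        lines = [ln for ln in f if ln.strip()]
    body = []
    for ln in lines:
        if ln.startswith("#"):
            key, _, value = ln[1:].strip().partition("\t")
            meta[key.strip()] = value
        elif not ln.startswith("x\t"):
            body.append([float(v) for v in ln.split()])
    arr = np.array(body)
    return FreeEnergyProfile(x=arr[:, 0], deltaG=arr[:, 1], mean_work=arr[:, 2],
                             dissipative_work=arr[:, 3],
                             n_used=int(meta.get("n_used", "0")))


def write_work_ensemble(works: WorkEnsemble, path: str) -> None:
    """First column x (nm), one column per trajectory (kJ/mol), TSV."""
    with open(path, "w") as f:
        f.write(f"# temperature\t{works.temperature!r}\n")
        f.write("x\t" + "\t".join(works.traj_ids) + "\n")
        np.savetxt(f, np.column_stack([works.x, works.works.T]),
                   delimiter="\t", fmt="%.10g")


def read_work_ensemble(path: str, temperature: float | None = None) -> WorkEnsemble:
    meta: dict[str, str] = {}
    header: list[str] = []
    body = []
    with open(path) as f:
        for ln in f:
            if ln.startswith("#"):
                key, _, value = ln[1:].strip().partition("\t")
                meta[key.strip()] = value
            elif not header:
                header = ln.rstrip("\n").split("\t")
            elif ln.strip():
                body.append([float(v) for v in ln.split()])
    arr = np.array(body)
    temp = temperature if temperature is not None else float(meta["temperature"])
    return WorkEnsemble(arr[:, 0], arr[:, 1:].T, temp, traj_ids=header[1:])
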