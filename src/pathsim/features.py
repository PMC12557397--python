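"""Trajectory data model and ligand-protein contact-distance extraction.

A biased unbinding trajectory is encoded as a ``K x M`` matrix of contact
distances: ``K`` saved frames by ``M`` contacts, where a contact is a protein
residue whose C-alpha atom approaches any ligand atom within a cutoff
(default 0.45 nm) at any point in the ensemble, and the feature value is the
minimal heavy-atom distance between the ligand and that residue.

Units are fixed throughout the package: distances in nm, time in ps,
energies in kJ/mol.  Converters belong at I/O boundaries only.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import h5py
import numpy as np

__all__ = [
    "ContactTrajectory",
    "TrajectoryEnsemble",
    "CoordinateFrameSet",
    "identify_contacts",
    "compute_contact_distances",
    "read_ensemble",
    "write_ensemble",
]

DEFAULT_CONTACT_CUTOFF = 0.45  # nm


@dataclass
class ContactTrajectory:
    """One trajectory's contact-distance matrix plus metadata.

    Parameters
    ----------
    values
        ``(K, M)`` array of contact distances in nm.  Raw (pre-preprocessing)
        values are nonnegative; preprocessed values (standardized, PCA) may
        not be, so only finiteness and shape are enforced here.
    dt
        Frame spacing in ps.
    traj_id
        Identifier of the trajectory.
    contact_labels
        ``M`` residue identifiers naming the feature columns.
    """

    values: np.ndarray
    dt: float = 1.0
    traj_id: str = ""
    contact_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("contact matrix must be 2-D (K time steps x M contacts)")
        k, m = self.values.shape
        if k < 2:
            raise ValueError(f"trajectory needs at least 2 frames, got K={k}")
        if m < 1:
            raise ValueError("trajectory needs at least 1 contact column")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite contact distances in trajectory {self.traj_id!r}")
        if not self.contact_labels:
            self.contact_labels = [f"contact_{j}" for j in range(m)]
        if len(self.contact_labels) != m:
            raise ValueError("contact_labels length does not match number of columns")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_contacts(self) -> int:
        return self.values.shape[1]


@dataclass
class TrajectoryEnsemble:
    """A set of N trajectories sharing one contact set.

    Frame counts K may differ between members (Wasserstein and DTW tolerate
    it); the contact columns must agree in number, labels and order.
    ``labels`` optionally carries a ground-truth pathway label per trajectory.
    """

    trajectories: list[ContactTrajectory]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.trajectories) < 2:
            raise ValueError("an ensemble needs at least 2 trajectories")
        ref = self.trajectories[0].contact_labels
        bad = [
            t.traj_id or str(i)
            for i, t in enumerate(self.trajectories)
            if t.contact_labels != ref
        ]
        if bad:
            raise ValueError(f"mismatched contact columns for trajectories: {bad}")
        if self.labels is not None and len(self.labels) != len(self.trajectories):
            raise ValueError("labels must have one entry per trajectory")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def __getitem__(self, i: int) -> ContactTrajectory:
        return self.trajectories[i]

    @property
    def n_contacts(self) -> int:
        return self.trajectories[0].n_contacts

    @property
    def contact_labels(self) -> list[str]:
        return self.trajectories[0].contact_labels

    @property
    def traj_ids(self) -> list[str]:
        return [t.traj_id or str(i) for i, t in enumerate(self.trajectories)]

    def equal_length(self) -> bool:
        k0 = self.trajectories[0].n_frames
        return all(t.n_frames == k0 for t in self.trajectories)

    def stacked(self) -> np.ndarray:
        """Return the (N, K, M) array; requires equal frame counts."""
        if not self.equal_length():
            raise ValueError("stacking requires trajectories of equal length")
        return np.stack([t.values for t in self.trajectories])

    def pooled(self) -> np.ndarray:
        """All frames of all trajectories concatenated, shape (sum K_i, M)."""
        return np.concatenate([t.values for t in self.trajectories], axis=0)

    def with_values(self, new_values: Sequence[np.ndarray],
                    contact_labels: list[str] | None = None) -> "TrajectoryEnsemble":
        """Copy of the ensemble with per-trajectory value matrices replaced."""
        labels = contact_labels or self.contact_labels
        trajs = [
            ContactTrajectory(v, dt=t.dt, traj_id=t.traj_id, contact_labels=list(labels))
            for v, t in zip(new_values, self.trajectories, strict=True)
        ]
        return TrajectoryEnsemble(trajs, labels=self.labels)


@dataclass
class CoordinateFrameSet:
    """Raw Cartesian coordinates (nm) from which contact features are derived.

    ``ligand`` is ``(T, A, 3)`` for A ligand heavy atoms; ``calpha`` is
    ``(T, R, 3)`` for R residues aligned with ``residue_ids``; ``heavy`` maps
    each residue id to its ``(T, H_r, 3)`` heavy-atom coordinates.  Residue
    ids follow the PDB convention of (chain, 1-based residue number) rendered
    as strings like ``"A:17"``, but any hashable, ordered id works.
    """

    ligand: np.ndarray
    calpha: np.ndarray
    heavy: Mapping[str, np.ndarray]
    residue_ids: list[str]

    def __post_init__(self) -> None:
        self.ligand = np.asarray(self.ligand, dtype=float)
        self.calpha = np.asarray(self.calpha, dtype=float)
        if self.ligand.ndim != 3 or self.ligand.shape[2] != 3:
            raise ValueError("ligand coordinates must be (T, A, 3)")
        if self.calpha.ndim != 3 or self.calpha.shape[2] != 3:
            raise ValueError("calpha coordinates must be (T, R, 3)")
        if self.calpha.shape[1] != len(self.residue_ids):
            raise ValueError("residue_ids must align with the calpha residue axis")
        t = self.ligand.shape[0]
        if self.calpha.shape[0] != t:
            raise ValueError("frame counts disagree between ligand and calpha arrays")
        for rid, xyz in self.heavy.items():
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape[0] != t or xyz.ndim != 3 or xyz.shape[2] != 3:
                raise ValueError(f"heavy-atom array for residue {rid} must be (T, H, 3)")
        if not (np.all(np.isfinite(self.ligand)) and np.all(np.isfinite(self.calpha))):
            raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.ligand.shape[0]


def identify_contacts(coords: CoordinateFrameSet,
                      cutoff: float = DEFAULT_CONTACT_CUTOFF) -> list[str]:
    """Find residues whose C-alpha comes within ``cutoff`` of any ligand atom.

    The search is a union over ALL frames: a residue qualifying in a single
    frame is a contact.  The boundary is inclusive (distance <= cutoff), the
    conventional choice for contact definitions.  Returns residue ids in
    their original (residue-index) order.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if coords.n_frames == 0:
        raise ValueError("no frames")
    # (T, R, A) pairwise distances C-alpha <-> ligand atoms
    diff = coords.calpha[:, :, None, :] - coords.ligand[:, None, :, :]
    dmin = np.sqrt((diff ** 2).sum(axis=-1)).min(axis=(0, 2))  # per residue over frames+atoms
    hit = dmin <= cutoff
    if not hit.any():
        raise ValueError("no contacts found")
    return [rid for rid, h in zip(coords.residue_ids, hit) if h]


def compute_contact_distances(coords: CoordinateFrameSet,
                              contacts: Sequence[str],
                              dt: float = 1.0,
                              traj_id: str = "") -> ContactTrajectory:
    """Minimal ligand/residue heavy-atom distance per frame for each contact.

    Entry ``(t, m)`` is the minimum Euclidean distance over all pairs of
    ligand heavy atoms and heavy atoms of contact residue ``m`` at frame
    ``t``, in nm.
    """
    if len(contacts) == 0:
        raise ValueError("contact set is empty")
    cols = []
    for rid in contacts:
        if rid not in coords.heavy:
            raise KeyError(f"residue {rid} has no heavy-atom coordinates")
        res = np.asarray(coords.heavy[rid], dtype=float)  # (T, H, 3)
        diff = coords.ligand[:, :, None, :] - res[:, None, :, :]
        cols.append(np.sqrt((diff ** 2).sum(axis=-1)).min(axis=(1, 2)))
    values = np.stack(cols, axis=1)
    return ContactTrajectory(values, dt=dt, traj_id=traj_id,
                             contact_labels=[str(r) for r in contacts])


def from_mdanalysis(universe, ligand_selection: str, protein_selection: str = "protein",
                    cutoff: float = DEFAULT_CONTACT_CUTOFF, dt: float | None = None,
                    traj_id: str = "") -> ContactTrajectory:
    """Thin adapter: extract contact distances from an MDAnalysis Universe.

    Optional convenience for standard MD formats (XTC/TRR/GRO/PDB); the core
    API consumes plain coordinate arrays.  MDAnalysis positions are in
    Angstrom and are converted to nm here.
    """
    prot = universe.select_atoms(f"({protein_selection}) and not name H*")
    lig = universe.select_atoms(f"({ligand_selection}) and not name H*")
    ca = universe.select_atoms(f"({protein_selection}) and name CA")
    rids = [f"{a.segid or 'A'}:{a.resid}" for a in ca]
    lig_xyz, ca_xyz = [], []
    heavy_idx = {rid: None for rid in rids}
    for rid, res_ca in zip(rids, ca):
        heavy_idx[rid] = prot.select_atoms(f"resid {res_ca.resid} and segid {res_ca.segid}") \
            if res_ca.segid else prot.select_atoms(f"resid {res_ca.resid}")
    heavy_xyz: dict[str, list] = {rid: [] for rid in rids}
    for _ in universe.trajectory:
        lig_xyz.append(lig.positions / 10.0)
        ca_xyz.append(ca.positions / 10.0)
        for rid in rids:
            heavy_xyz[rid].append(heavy_idx[rid].positions / 10.0)
    frames = CoordinateFrameSet(
        ligand=np.array(lig_xyz), calpha=np.array(ca_xyz),
        heavy={rid: np.array(v) for rid, v in heavy_xyz.items()}, residue_ids=rids,
    )
    contacts = identify_contacts(frames, cutoff=cutoff)
    if dt is None:
        dt = float(getattr(universe.trajectory, "dt", 1.0))
    return compute_contact_distances(frames, contacts, dt=dt, traj_id=traj_id)


# ---------------------------------------------------------------------------
# Ensemble container I/O
# ---------------------------------------------------------------------------

def write_ensemble(ensemble: TrajectoryEnsemble, path: str, format: str = "hdf5") -> None:
    """Write an ensemble container (``hdf5`` file or ``csv`` directory)."""
    if format == "hdf5":
        _write_hdf5(ensemble, path)
    elif format == "csv":
        _write_csv_dir(ensemble, path)
    else:
        raise ValueError(f"unknown ensemble format {format!r}")


def read_ensemble(path: str, format: str = "hdf5") -> TrajectoryEnsemble:
    """Read an ensemble container written by :func:`write_ensemble`."""
    if format == "hdf5":
        return _read_hdf5(path)
    if format == "csv":
        return _read_csv_dir(path)
    raise ValueError(f"unknown ensemble format {format!r}")


def _write_hdf5(ensemble: TrajectoryEnsemble, path: str) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("trajectories")
        for i, t in enumerate(ensemble.trajectories):
            ds = grp.create_dataset(f"{i:06d}", data=t.values, dtype="float64")
            ds.attrs["dt"] = t.dt
            ds.attrs["traj_id"] = t.traj_id or str(i)
        f.create_dataset("contact_labels",
                         data=np.array(ensemble.contact_labels, dtype=h5py.string_dtype()))
        if ensemble.labels is not None:
            f.create_dataset("labels",
                             data=np.array(ensemble.labels, dtype=h5py.string_dtype()))


def _read_hdf5(path: str) -> TrajectoryEnsemble:
    with h5py.File(path, "r") as f:
        contact_labels = [s.decode() for s in f["contact_labels"][()]]
        trajs = []
        for key in sorted(f["trajectories"]):
            ds = f["trajectories"][key]
            values = ds[()]
            if not np.all(np.isfinite(values)):
                raise ValueError(f"non-finite entries in stored trajectory {key}")
            trajs.append(ContactTrajectory(values, dt=float(ds.attrs["dt"]),
                                           traj_id=str(ds.attrs["traj_id"]),
                                           contact_labels=list(contact_labels)))
        labels = [s.decode() for s in f["labels"][()]] if "labels" in f else None
    return TrajectoryEnsemble(trajs, labels=labels)


def _write_csv_dir(ensemble: TrajectoryEnsemble, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    manifest = os.path.join(path, "manifest.tsv")
    with open(manifest, "w", newline="") as mf:
        w = csv.writer(mf, delimiter="\t")
        w.writerow(["traj_id", "path", "dt", "label"])
        for i, t in enumerate(ensemble.trajectories):
            fname = f"traj_{i:06d}.csv"
            label = ensemble.labels[i] if ensemble.labels is not None else ""
            w.writerow([t.traj_id or str(i), fname, repr(t.dt), label])
            with open(os.path.join(path, fname), "w", newline="") as tf:
                tw = csv.writer(tf)
                tw.writerow(ensemble.contact_labels)
                tw.writerows(t.values.tolist())


def _read_csv_dir(path: str) -> TrajectoryEnsemble:
    manifest = os.path.join(path, "manifest.tsv")
    trajs, labels, any_label = [], [], False
    with open(manifest, newline="") as mf:
        for row in csv.DictReader(mf, delimiter="\t"):
            with open(os.path.join(path, row["path"]), newline="") as tf:
                r = csv.reader(tf)
                contact_labels = next(r)
                values = np.array([[float(x) for x in line] for line in r])
            if not np.all(np.isfinite(values)):
                raise ValueError(f"non-finite entries in {row['path']}")
            trajs.append(ContactTrajectory(values, dt=float(row["dt"]),
                                           traj_id=row["traj_id"],
                                           contact_labels=contact_labels))
            labels.append(row.get("label", ""))
            any_label = any_label or bool(row.get("label"))
    return TrajectoryEnsemble(trajs, labels=labels if any_label else None)
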