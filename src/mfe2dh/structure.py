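"""Coordinate containers and trajectory I/O.

A trajectory is stored column-wise: one :class:`Topology` (per-atom chain,
residue and atom identity, shared by every frame) plus a dense coordinate
array of shape ``(n_frames, n_atoms, 3)`` in Å.  This mirrors how MD analysis
libraries hold ensembles and keeps per-frame hydrogen-bond tracing a pure
numpy operation.

Supported on-disk formats:

* multi-model PDB (``MODEL``/``ENDMDL`` blocks, or a single model), read and
  written through :mod:`biotite`;
* a plain whitespace table dialect with header
  ``frame time_ps chain resnum resname atom x y z`` for hand-editable
  fixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "StructureError",
    "MissingAtomError",
    "read_multimodel_pdb",
    "write_trajectory",
    "read_table_trajectory",
    "write_table_trajectory",
    "select_atom",
    "DEFAULT_FRAME_SPACING_PS",
]

#: Frame spacing assumed when a file carries no time metadata.  500 frames at
#: 100 ps/frame span 50 ns, the length of the production runs being emulated.
DEFAULT_FRAME_SPACING_PS = 100.0


class StructureError(ValueError):
    """Malformed structure file or inconsistent trajectory."""


class MissingAtomError(KeyError):
    """An atom address (chain, residue, atom name) could not be resolved."""

    def __str__(self) -> str:  # KeyError quotes its message by default
        return self.args[0] if self.args else ""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one frame: identity plus coordinates in Å."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise StructureError(
                f"atom {self.chain_id}/{self.residue_number}/{self.atom_name}: "
                "coordinates must be a finite 3-vector"
            )
        if self.residue_number < 1:
            raise StructureError("residue_number must be >= 1")
        object.__setattr__(self, "coordinates", coords)


class Topology:
    """Per-atom identity shared by all frames of a trajectory."""

    def __init__(
        self,
        chain_ids: Sequence[str],
        residue_numbers: Sequence[int],
        residue_names: Sequence[str],
        atom_names: Sequence[str],
        elements: Sequence[str] | None = None,
    ) -> None:
        self.chain_ids = np.asarray(chain_ids, dtype="U4")
        self.residue_numbers = np.asarray(residue_numbers, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype="U4")
        self.atom_names = np.asarray(atom_names, dtype="U6")
        if elements is None:
            elements = [_guess_element(name) for name in self.atom_names]
        self.elements = np.asarray(elements, dtype="U2")
        n = len(self.chain_ids)
        for arr, what in [
            (self.residue_numbers, "residue_numbers"),
            (self.residue_names, "residue_names"),
            (self.atom_names, "atom_names"),
            (self.elements, "elements"),
        ]:
            if len(arr) != n:
                raise StructureError(f"{what} length {len(arr)} != {n} atoms")
        if np.any(self.residue_numbers < 1):
            raise StructureError("residue numbers must be >= 1")
        self._index: dict[tuple[str, int, str], int] | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.chain_ids)

    @property
    def chains(self) -> list[str]:
        """Chain labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c), None)
        return list(seen)

    def _build_index(self) -> dict[tuple[str, int, str], int]:
        if self._index is None:
            index: dict[tuple[str, int, str], int] = {}
            for i in range(self.n_atoms):
                key = (str(self.chain_ids[i]), int(self.residue_numbers[i]), str(self.atom_names[i]))
                if key in index:
                    raise StructureError(
                        f"duplicate atom address chain {key[0]} residue {key[1]} atom {key[2]}"
                    )
                index[key] = i
            self._index = index
        return self._index

    def index_of(self, chain: str, residue_number: int, atom_name: str) -> int:
        """Index of the unique atom at an address, or raise MissingAtomError."""
        try:
            return self._build_index()[(str(chain), int(residue_number), str(atom_name))]
        except KeyError:
            raise MissingAtomError(
                f"no atom named {atom_name!r} in chain {chain!r} residue {residue_number}"
            ) from None

    def residue_atom_names(self, chain: str, residue_number: int) -> list[str]:
        mask = (self.chain_ids == str(chain)) & (self.residue_numbers == int(residue_number))
        return [str(a) for a in self.atom_names[mask]]

    def same_identity(self, other: "Topology") -> bool:
        return (
            self.n_atoms == other.n_atoms
            and bool(np.all(self.chain_ids == other.chain_ids))
            and bool(np.all(self.residue_numbers == other.residue_numbers))
            and bool(np.all(self.atom_names == other.atom_names))
        )


@dataclass
class Frame:
    """One snapshot: a topology plus coordinates ``(n_atoms, 3)`` at a time in ps."""

    topology: Topology
    coords: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise StructureError(
                f"coordinate array shape {self.coords.shape} does not match "
                f"{self.topology.n_atoms} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates in frame")
        if self.time < 0:
            raise StructureError("frame time must be >= 0 ps")

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def atom(self, index: int) -> AtomRecord:
        top = self.topology
        return AtomRecord(
            chain_id=str(top.chain_ids[index]),
            residue_number=int(top.residue_numbers[index]),
            residue_name=str(top.residue_names[index]),
            atom_name=str(top.atom_names[index]),
            element=str(top.elements[index]),
            coordinates=self.coords[index].copy(),
        )

    def select_atom(self, chain: str, residue_number: int, atom_name: str) -> AtomRecord:
        return self.atom(self.topology.index_of(chain, residue_number, atom_name))


@dataclass
class Trajectory:
    """An ordered ensemble of frames over a shared topology.

    ``coords`` has shape ``(n_frames, n_atoms, 3)``; ``times`` are strictly
    increasing picoseconds.  ``label`` names the variant the ensemble belongs
    to (NATIVE, T15A, N158D, E232K, R248C, W249G, or anything else).
    """

    topology: Topology
    coords: np.ndarray
    times: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError("trajectory coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise StructureError("trajectory must contain at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise StructureError("coords second axis does not match topology atom count")
        if self.times.shape != (self.coords.shape[0],):
            raise StructureError("times length does not match frame count")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise StructureError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> Frame:
        return Frame(self.topology, self.coords[i], float(self.times[i]))

    def frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self[i]

    @classmethod
    def from_frames(cls, frames: Sequence[Frame], label: str = "") -> "Trajectory":
        if not frames:
            raise StructureError("cannot build a trajectory from zero frames")
        top = frames[0].topology
        for k, fr in enumerate(frames[1:], start=1):
            if not fr.topology.same_identity(top):
                raise StructureError(f"frame {k} atom identity differs from frame 0")
        coords = np.stack([fr.coords for fr in frames])
        times = np.array([fr.time for fr in frames], dtype=float)
        return cls(top, coords, times, label=label)


def select_atom(frame: Frame, chain: str, residue_number: int, atom_name: str) -> AtomRecord:
    """The unique atom at (chain, residue, atom name) in ``frame``."""
    return frame.select_atom(chain, residue_number, atom_name)


def _guess_element(atom_name: str) -> str:
    stripped = str(atom_name).strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


# ---------------------------------------------------------------------------
# multi-model PDB
# ---------------------------------------------------------------------------

def _prescan_pdb(path: Path) -> None:
    """Pre-validate MODEL blocks so errors carry the offending model index /
    line number, which the underlying library does not report."""
    counts: list[int] = []
    current: int | None = None
    saw_model = False
    n_atoms_single = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("MODEL"):
                saw_model = True
                current = 0
            elif line.startswith("ENDMDL"):
                if current is not None:
                    counts.append(current)
                    current = None
            elif line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise StructureError(f"{path}: unparseable ATOM record at line {lineno}")
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                    int(line[22:26])
                except ValueError:
                    raise StructureError(
                        f"{path}: unparseable ATOM record at line {lineno}"
                    ) from None
                if saw_model:
                    if current is None:  # atoms after ENDMDL, outside any block
                        raise StructureError(
                            f"{path}: ATOM record outside MODEL block at line {lineno}"
                        )
                    current += 1
                else:
                    n_atoms_single += 1
    if saw_model:
        if current is not None:  # unterminated final MODEL: tolerate
            counts.append(current)
        ref = counts[0] if counts else 0
        for i, c in enumerate(counts, start=1):
            if c != ref:
                raise StructureError(
                    f"{path}: model {i} has {c} atoms, expected {ref} (model 1)"
                )
        if ref == 0:
            raise StructureError(f"{path}: no ATOM records found")
    elif n_atoms_single == 0:
        raise StructureError(f"{path}: no ATOM records found")


def read_multimodel_pdb(
    path: str | Path,
    frame_spacing_ps: float = DEFAULT_FRAME_SPACING_PS,
    label: str = "",
) -> Trajectory:
    """Read a (multi-)model PDB file into a :class:`Trajectory`.

    Models become frames in file order.  PDB carries no time stamps, so frame
    times are assigned as ``i * frame_spacing_ps``.  Alternate locations and
    insertion codes are ignored (first altloc kept) with a warning.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_pdb(path)

    pdbfile = PDBFile.read(str(path))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stack = pdbfile.get_structure(model=None, altloc="first")
    # biotite returns an AtomArray for single-model files
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None, :, :]
    top = Topology(
        chain_ids=[str(c) for c in stack.chain_id],
        residue_numbers=[int(r) for r in stack.res_id],
        residue_names=[str(r) for r in stack.res_name],
        atom_names=[str(a) for a in stack.atom_name],
        elements=[str(e) if str(e) else _guess_element(a) for e, a in zip(stack.element, stack.atom_name)],
    )
    times = np.arange(coords.shape[0], dtype=float) * float(frame_spacing_ps)
    return Trajectory(top, coords, times, label=label or path.stem)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a standard multi-model PDB (3-decimal coords)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if not isinstance(traj, Trajectory):
        raise TypeError("write_trajectory expects a Trajectory")
    stack = struc.AtomArrayStack(traj.n_frames, traj.n_atoms)
    stack.chain_id = traj.topology.chain_ids.astype("U4")
    stack.res_id = traj.topology.residue_numbers.astype(int)
    stack.res_name = traj.topology.residue_names.astype("U5")
    stack.atom_name = traj.topology.atom_names.astype("U6")
    stack.element = traj.topology.elements.astype("U2")
    stack.hetero = np.zeros(traj.n_atoms, dtype=bool)
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    pdbfile = PDBFile()
    pdbfile.set_structure(stack)
    pdbfile.write(str(path))


# ---------------------------------------------------------------------------
# plain-table dialect
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["frame", "time_ps", "chain", "resnum", "resname", "atom", "x", "y", "z"]


def read_table_trajectory(path: str | Path, label: str = "") -> Trajectory:
    """Read the whitespace-table trajectory dialect.

    Expected header: ``frame time_ps chain resnum resname atom x y z``.
    """
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise StructureError(f"{path}: table dialect missing columns {missing}")
    frames = []
    first_top: Topology | None = None
    for fidx, grp in df.groupby("frame", sort=True):
        top = Topology(
            chain_ids=grp["chain"].astype(str).tolist(),
            residue_numbers=grp["resnum"].astype(int).tolist(),
            residue_names=grp["resname"].astype(str).tolist(),
            atom_names=grp["atom"].astype(str).tolist(),
        )
        if first_top is None:
            first_top = top
        elif not top.same_identity(first_top):
            raise StructureError(f"{path}: frame {fidx} atom identity differs from first frame")
        coords = grp[["x", "y", "z"]].to_numpy(dtype=float)
        frames.append(Frame(first_top, coords, float(grp["time_ps"].iloc[0])))
    if not frames:
        raise StructureError(f"{path}: empty trajectory table")
    return Trajectory.from_frames(frames, label=label or path.stem)


def write_table_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write the whitespace-table trajectory dialect (round-trips with
    :func:`read_table_trajectory`)."""
    import pandas as pd

    top = traj.topology
    rows = []
    for f in range(traj.n_frames):
        rows.append(
            pd.DataFrame(
                {
                    "frame": f,
                    "time_ps": traj.times[f],
                    "chain": top.chain_ids,
                    "resnum": top.residue_numbers,
                    "resname": top.residue_names,
                    "atom": top.atom_names,
                    "x": traj.coords[f, :, 0],
                    "y": traj.coords[f, :, 1],
                    "z": traj.coords[f, :, 2],
                }
            )
        )
    pd.concat(rows).to_csv(path, sep="\t", index=False, float_format="%.3f")
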