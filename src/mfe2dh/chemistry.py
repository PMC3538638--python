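"""Heavy-atom hydrogen-bond chemistry for standard amino acids.

Only donor/acceptor *heavy* atoms are tabulated: the bond criterion used
throughout the package is the donor–acceptor distance, so explicit hydrogens
are never required.  Backbone N donates (except proline); backbone O accepts.
Atoms that carry both a polar hydrogen and a lone pair (Ser/Thr/Tyr
hydroxyls, His ring nitrogens) appear in both sets.
"""

from __future__ import annotations

import warnings

__all__ = [
    "SIDECHAIN_DONORS",
    "SIDECHAIN_ACCEPTORS",
    "GROUP_SHORTHAND",
    "STANDARD_RESIDUES",
    "enumerate_donors_acceptors",
]

SIDECHAIN_DONORS: dict[str, frozenset[str]] = {
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "ASN": frozenset({"ND2"}),
    "GLN": frozenset({"NE2"}),
    "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "TRP": frozenset({"NE1"}),
    "HIS": frozenset({"ND1", "NE2"}),
}

SIDECHAIN_ACCEPTORS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "ASN": frozenset({"OD1"}),
    "GLN": frozenset({"OE1"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "HIS": frozenset({"ND1", "NE2"}),
}

#: Atom-group shorthand as used in bond tables ("R251 NH", "E181 OE"):
#: the monitored distance is the minimum over the named group.
GROUP_SHORTHAND: dict[str, tuple[str, ...]] = {
    "NH": ("NH1", "NH2"),
    "OE": ("OE1", "OE2"),
    "OD": ("OD1", "OD2"),
}

STANDARD_RESIDUES: frozenset[str] = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)

AtomAddress = tuple[str, int, str]


def enumerate_donors_acceptors(frame) -> tuple[set[AtomAddress], set[AtomAddress]]:
    """All hydrogen-bond donor and acceptor heavy atoms present in a frame.

    Returns two sets of addresses ``(chain, residue_number, atom_name)``.
    Residues with names outside the 20 standard amino acids are skipped with
    a warning.  Only atoms actually present in the frame are reported, so a
    truncated side chain simply contributes fewer candidates.
    """
    top = frame.topology
    donors: set[AtomAddress] = set()
    acceptors: set[AtomAddress] = set()
    warned: set[str] = set()
    for i in range(top.n_atoms):
        resname = str(top.residue_names[i])
        if resname not in STANDARD_RESIDUES:
            if resname not in warned:
                warnings.warn(f"unknown residue name {resname!r}: skipped", stacklevel=2)
                warned.add(resname)
            continue
        addr: AtomAddress = (
            str(top.chain_ids[i]),
            int(top.residue_numbers[i]),
            str(top.atom_names[i]),
        )
        name = addr[2]
        if name == "N" and resname != "PRO":
            donors.add(addr)
        elif name == "O":
            acceptors.add(addr)
        if name in SIDECHAIN_DONORS.get(resname, ()):  # side-chain donors
            donors.add(addr)
        if name in SIDECHAIN_ACCEPTORS.get(resname, ()):  # side-chain acceptors
            acceptors.add(addr)
    return donors, acceptors
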