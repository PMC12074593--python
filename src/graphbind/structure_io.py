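"""Read protein structures into ordered residue chains with C-alpha coordinates.

Only standard polymer amino acids are retained; hetero residues, waters and
residues lacking a C-alpha record are excluded, because the contact graph is
defined purely over C-alpha positions. Residue indices are the 1-based author
numbers from the file; node order inside a graph is 0-based chain order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from graphbind.errors import ChainLookupError, EmptyChainError, LabelingError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Residue:
    """One retained residue: author index, one-letter code, C-alpha position, label."""

    residue_index: int
    aa_code: str
    ca_xyz: tuple[float, float, float]
    label: int | None = None


@dataclass(frozen=True)
class ResidueChain:
    """Ordered residues of one protein chain.

    Invariants: ``residue_index`` strictly increasing; every residue has a
    C-alpha coordinate; labels, when attached, cover every retained residue.
    """

    chain_id: str
    residues: tuple[Residue, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        idx = [r.residue_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa_code for r in self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(L, 3) C-alpha coordinates in Angstroms."""
        return np.array([r.ca_xyz for r in self.residues], dtype=float).reshape(-1, 3)

    @property
    def labels(self) -> np.ndarray | None:
        """(L,) binary labels, or None when not all residues are labeled."""
        if any(r.label is None for r in self.residues) or not self.residues:
            return None
        return np.array([r.label for r in self.residues], dtype=int)


def _best_ca(residue: gemmi.Residue) -> gemmi.Atom | None:
    """Highest-occupancy CA atom among alternate locations, if any."""
    best = None
    for atom in residue:
        if atom.name == "CA" and atom.element.name == "C":
            if best is None or atom.occ > best.occ:
                best = atom
    return best


def read_structure(path: str | Path, chain_id: str) -> ResidueChain:
    """Parse a PDB or mmCIF file and return one chain as a :class:`ResidueChain`.

    Residues without a C-alpha atom are dropped with a warning; alternate
    conformations resolve to the highest-occupancy CA. Non-polymer residues
    (waters, ligands, non-standard hetero groups) are excluded.

    Raises
    ------
    FileNotFoundError, ChainLookupError, EmptyChainError
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    model = structure[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ChainLookupError(f"chain {chain_id!r} not found in {path.name}; "
                               f"available: {[c.name for c in model]}")
    residues: list[Residue] = []
    for res in chain:
        info = gemmi.find_tabulated_residue(res.name)
        if info is None or not info.is_amino_acid() or not info.is_standard():
            continue
        ca = _best_ca(res)
        if ca is None:
            logger.warning("residue %s %d in chain %s has no CA atom; dropped",
                           res.name, res.seqid.num, chain_id)
            continue
        residues.append(Residue(
            residue_index=res.seqid.num,
            aa_code=info.one_letter_code.upper(),
            ca_xyz=(ca.pos.x, ca.pos.y, ca.pos.z),
        ))
    if not residues:
        raise EmptyChainError(f"chain {chain_id!r} of {path.name} has no residue with a CA atom")
    return ResidueChain(chain_id=chain_id, residues=tuple(residues))


def read_label_file(path: str | Path) -> dict[int, int]:
    """Read a label sidecar.

    Two accepted layouts: two whitespace-separated columns
    ``residue_index label`` (one residue per line), or a single 0/1 string of
    length L which is mapped positionally to the chain at attach time (keyed
    from 1). Values outside {0, 1} are rejected.
    """
    text = Path(path).read_text().split()
    if not text:
        raise LabelingError(f"empty label file: {path}")
    if len(text) == 1 and set(text[0]) <= {"0", "1"} and len(text[0]) > 1:
        return {i + 1: int(c) for i, c in enumerate(text[0])}
    if len(text) % 2:
        raise LabelingError(f"label file {path} is not two-column index/label text")
    labels: dict[int, int] = {}
    for idx_s, lab_s in zip(text[::2], text[1::2]):
        try:
            idx, lab = int(idx_s), int(lab_s)
        except ValueError as exc:
            raise LabelingError(f"non-integer entry in label file {path}: {idx_s} {lab_s}") from exc
        if lab not in (0, 1):
            raise LabelingError(f"label for residue {idx} is {lab}; must be 0 or 1")
        labels[idx] = lab
    return labels


def attach_labels(chain: ResidueChain, labels: dict[int, int] | str | Path) -> ResidueChain:
    """Return a copy of ``chain`` with a binary label on every residue.

    ``labels`` maps residue_index -> {0, 1} (or is a path to a sidecar file).
    A positional 0/1 string file of exactly length L is also accepted and
    aligned to chain order. Every retained residue must receive a label;
    there is no silent default.
    """
    if not isinstance(labels, dict):
        labels = read_label_file(labels)
    if any(v not in (0, 1) for v in labels.values()):
        raise LabelingError("labels must be 0 or 1")
    keys = set(labels)
    chain_idx = [r.residue_index for r in chain.residues]
    if keys == set(range(1, len(chain) + 1)) and keys != set(chain_idx):
        # positional string aligned to chain order rather than author numbering
        labels = {ri: labels[pos + 1] for pos, ri in enumerate(chain_idx)}
    missing = [ri for ri in chain_idx if ri not in labels]
    if missing:
        raise LabelingError(f"no label for residues {missing[:10]}"
                            f"{'...' if len(missing) > 10 else ''} of chain {chain.chain_id}")
    extra = set(labels) - set(chain_idx)
    if extra:
        raise LabelingError(f"labels reference residues absent from chain "
                            f"{chain.chain_id}: {sorted(extra)[:10]}")
    return ResidueChain(
        chain_id=chain.chain_id,
        residues=tuple(replace(r, label=int(labels[r.residue_index])) for r in chain.residues),
    )
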