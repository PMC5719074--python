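"""Ionic contact mapping across a core-particle / regulator interface.

A salt bridge is called when an acidic side-chain oxygen (Glu OE1/OE2, Asp
OD1/OD2, optionally the C-terminal OXT) lies within a cutoff — 4.0 Å by the
standard convention — of a basic side-chain nitrogen (Lys NZ, Arg
NE/NH1/NH2; His ND1/NE2 optional).  Contacts are reported at residue-pair
level, keeping the closest atom pair, with the acidic partner listed first
(for a proteasome complex, pass the core-particle chains as ``group_a``).

The module also transfers interface residues to homologous sequences by
global pairwise alignment, computes carboxylate-centroid site geometry, and
scores 4-residue subsets against the square charge arrangement of an
idealized tetra-cationic porphyrin.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from Bio import Align
from Bio.Align import substitution_matrices

from .structure import ResKey, Structure, THREE_TO_ONE

__all__ = [
    "NEGATIVE_ATOMS",
    "POSITIVE_ATOMS",
    "IonicContact",
    "InterfaceMap",
    "ResidueMapping",
    "TransferReport",
    "SiteGeometry",
    "SquareMatch",
    "find_ionic_contacts",
    "build_interface_map",
    "align_and_map",
    "transfer_contacts",
    "site_geometry",
    "match_ligand_geometry",
    "square_match_score",
    "ideal_square_distances",
]

NEGATIVE_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
POSITIVE_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
_HIS_ATOMS = {"HIS": ("ND1", "NE2")}


@dataclass(frozen=True)
class ContactAtom:
    chain: str
    position: int
    icode: str
    res_name: str
    atom_name: str

    @property
    def res_key(self) -> ResKey:
        return (self.chain, self.position, self.icode)


@dataclass(frozen=True)
class IonicContact:
    negative: ContactAtom
    positive: ContactAtom
    distance: float


@dataclass
class InterfaceMap:
    """Contacts plus their grouping into inter-subunit grooves."""

    contacts: list[IonicContact]
    groove_groups: dict[str, list[ResKey]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {g: len(r) for g, r in self.groove_groups.items()}

    def unique_negative_residues(self) -> list[ResKey]:
        seen: dict[ResKey, None] = {}
        for c in self.contacts:
            seen.setdefault(c.negative.res_key, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "neg_chain": c.negative.chain, "neg_pos": c.negative.position,
                "neg_res": c.negative.res_name, "neg_atom": c.negative.atom_name,
                "pos_chain": c.positive.chain, "pos_pos": c.positive.position,
                "pos_res": c.positive.res_name, "pos_atom": c.positive.atom_name,
                "distance_A": c.distance,
            }
            for c in self.contacts
        ]
        return pd.DataFrame(rows)


def _charged_atoms(struct: Structure, chains: set[str], polarity: str,
                   include_his: bool, include_termini: bool):
    """(atoms, coords) of charged side-chain atoms of one polarity."""
    table = dict(NEGATIVE_ATOMS) if polarity == "neg" else dict(POSITIVE_ATOMS)
    if polarity == "pos" and include_his:
        table.update(_HIS_ATOMS)
    out, xyz = [], []
    for a in struct.atoms:
        if a.chain not in chains:
            continue
        names = table.get(a.res_name)
        hit = names is not None and a.name in names
        if polarity == "neg" and include_termini and a.name == "OXT":
            hit = True
        if hit:
            out.append(ContactAtom(a.chain, a.res_seq, a.icode, a.res_name, a.name))
            xyz.append(a.xyz)
    return out, np.array(xyz, dtype=float).reshape(-1, 3)


def find_ionic_contacts(struct: Structure, group_a: Iterable[str],
                        group_b: Iterable[str], cutoff: float = 4.0,
                        include_his: bool = False,
                        include_termini: bool = False) -> list[IonicContact]:
    """All inter-group ionic contacts within ``cutoff`` Å.

    Both polarities of each group are scanned (acidic in ``group_a`` against
    basic in ``group_b`` and vice versa), and every contact is reported with
    its acidic partner first; deduplication keeps the minimum-distance atom
    pair per residue pair.  Contacts are sorted by distance.  A k-d tree does
    the neighbour search; results are identical to an all-pairs scan.
    """
    ga, gb = set(group_a), set(group_b)
    if not ga or not gb:
        raise ValueError("both chain groups must be non-empty")
    if ga & gb:
        raise ValueError(f"chain groups overlap: {sorted(ga & gb)}")
    if cutoff <= 0:
        return []

    best: dict[tuple[ResKey, ResKey], IonicContact] = {}
    for neg_chains, pos_chains in ((ga, gb), (gb, ga)):
        negs, nxyz = _charged_atoms(struct, neg_chains, "neg",
                                    include_his, include_termini)
        poss, pxyz = _charged_atoms(struct, pos_chains, "pos",
                                    include_his, include_termini)
        if not negs or not poss:
            continue
        tree = cKDTree(pxyz)
        for i, neighbours in enumerate(tree.query_ball_point(nxyz, cutoff)):
            for j in neighbours:
                d = float(np.linalg.norm(nxyz[i] - pxyz[j]))
                key = (negs[i].res_key, poss[j].res_key)
                cur = best.get(key)
                if cur is None or d < cur.distance:
                    best[key] = IonicContact(negs[i], poss[j], d)
    return sorted(best.values(), key=lambda c: (c.distance, c.negative.res_key,
                                                c.positive.res_key))


def build_interface_map(contacts: Sequence[IonicContact],
                        groove_by_chain: Optional[dict[str, str]] = None,
                        ) -> InterfaceMap:
    """Group contacts by inter-subunit groove.

    ``groove_by_chain`` maps each core (acidic-side) chain to a groove label
    supplied by the caller from the complex's subunit annotation (e.g.
    chains of the α4 and α5 subunits both to "α4-α5"); no ring topology is
    hard-coded.  Unannotated chains fall into the "" group.  Each groove
    lists its unique acidic residues.
    """
    groove_by_chain = groove_by_chain or {}
    groups: dict[str, dict[ResKey, None]] = {}
    for c in contacts:
        label = groove_by_chain.get(c.negative.chain, "")
        groups.setdefault(label, {}).setdefault(c.negative.res_key, None)
    return InterfaceMap(
        contacts=list(contacts),
        groove_groups={g: list(keys) for g, keys in groups.items()},
    )


# ---------------------------------------------------------------------------
# Homolog transfer
# ---------------------------------------------------------------------------

_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class ResidueMapping:
    """Aligned position pairs between a template and a target sequence.

    ``pairs`` maps template position -> (target position, template aa,
    target aa, identical).  Positions refer to the supplied numbering (by
    default 1-based sequence positions); positions aligned to gaps are
    absent.  The mapping is injective and order-preserving by construction
    (it comes from a global alignment).
    """

    pairs: dict[int, tuple[int, str, str, bool]]
    template_seq: str
    target_seq: str
    score: float


def align_and_map(template_seq: str, target_seq: str,
                  template_numbering: Optional[Sequence[int]] = None,
                  target_numbering: Optional[Sequence[int]] = None,
                  ) -> ResidueMapping:
    """Global alignment (BLOSUM62, gap open 10 / extend 0.5) position map.

    Custom numbering sequences (e.g. author residue numbers from a
    structure) may be supplied; they must match the sequence lengths.
    """
    for s in (template_seq, target_seq):
        if not s:
            raise ValueError("sequences must be non-empty")
        bad = set(s.upper()) - _AA
        if bad:
            raise ValueError(f"illegal sequence characters: {sorted(bad)}")
    template_seq = template_seq.upper()
    target_seq = target_seq.upper()
    if template_numbering is None:
        template_numbering = range(1, len(template_seq) + 1)
    if target_numbering is None:
        target_numbering = range(1, len(target_seq) + 1)
    template_numbering = list(template_numbering)
    target_numbering = list(target_numbering)
    if len(template_numbering) != len(template_seq):
        raise ValueError("template numbering length mismatch")
    if len(target_numbering) != len(target_seq):
        raise ValueError("target numbering length mismatch")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(template_seq, target_seq)[0]

    pairs: dict[int, tuple[int, str, str, bool]] = {}
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        for off in range(te - ts):
            ti, qi = ts + off, qs + off
            ta, qa = template_seq[ti], target_seq[qi]
            pairs[template_numbering[ti]] = (target_numbering[qi], ta, qa, ta == qa)
    return ResidueMapping(pairs, template_seq, target_seq, float(aln.score))


@dataclass
class TransferReport:
    kept: int = 0
    dropped_gap: int = 0
    dropped_nonacidic: int = 0
    dropped_unmapped_positive: int = 0

    @property
    def dropped(self) -> int:
        return self.dropped_gap + self.dropped_nonacidic + self.dropped_unmapped_positive


_ACIDIC_LETTERS = {"D", "E"}


def transfer_contacts(imap: InterfaceMap,
                      mappings: dict[str, ResidueMapping],
                      target_struct: Optional[Structure] = None,
                      groove_by_chain: Optional[dict[str, str]] = None,
                      ) -> tuple[InterfaceMap, TransferReport]:
    """Re-index an interface map onto homologous target numbering.

    Every contact chain must have a mapping.  Contacts whose acidic residue
    aligns to a gap or to a non-Asp/Glu target residue are dropped and
    counted; contacts whose basic residue is unmapped are likewise dropped
    (counted separately).  Distances are carried over from the template
    (``target_struct``, when given, is used only to verify residue
    identities by author numbering).
    """
    report = TransferReport()
    out: list[IonicContact] = []
    target_res = target_struct.residues() if target_struct is not None else None

    def target_letter(chain: str, pos: int, aligned_letter: str) -> str:
        if target_res is not None:
            name = target_res.get((chain, pos, ""))
            if name is not None:
                return THREE_TO_ONE.get(name, "X")
        return aligned_letter

    for c in imap.contacts:
        for atom in (c.negative, c.positive):
            if atom.chain not in mappings:
                raise KeyError(f"no residue mapping for chain {atom.chain!r}")
        neg_hit = mappings[c.negative.chain].pairs.get(c.negative.position)
        if neg_hit is None:
            report.dropped_gap += 1
            continue
        tgt_pos, _, tgt_aa, _ = neg_hit
        if target_letter(c.negative.chain, tgt_pos, tgt_aa) not in _ACIDIC_LETTERS:
            report.dropped_nonacidic += 1
            continue
        pos_hit = mappings[c.positive.chain].pairs.get(c.positive.position)
        if pos_hit is None:
            report.dropped_unmapped_positive += 1
            continue
        report.kept += 1
        out.append(IonicContact(
            negative=ContactAtom(c.negative.chain, tgt_pos, c.negative.icode,
                                 c.negative.res_name, c.negative.atom_name),
            positive=ContactAtom(c.positive.chain, pos_hit[0], c.positive.icode,
                                 c.positive.res_name, c.positive.atom_name),
            distance=c.distance,
        ))
    return build_interface_map(out, groove_by_chain), report


# ---------------------------------------------------------------------------
# Site geometry and ligand matching
# ---------------------------------------------------------------------------


@dataclass
class SiteGeometry:
    """Carboxylate charge centroids and their pairwise distance matrix (Å)."""

    keys: list[ResKey]
    centroids: np.ndarray          # (n, 3)
    distances: np.ndarray          # (n, n), symmetric, zero diagonal


def site_geometry(struct: Structure, residues: Sequence[ResKey]) -> SiteGeometry:
    """Centroid (mean of the carboxylate oxygens) per acidic residue plus the
    full pairwise Euclidean distance matrix."""
    names = struct.residues()
    cents = []
    for key in residues:
        res_name = names.get(key)
        if res_name is None:
            raise KeyError(f"residue {key} not in structure")
        ox_names = NEGATIVE_ATOMS.get(res_name)
        if ox_names is None:
            raise ValueError(f"residue {key} ({res_name}) is not Asp/Glu")
        ox = [a.xyz for a in struct.atoms_of(key) if a.name in ox_names]
        if not ox:
            raise ValueError(f"residue {key} is missing carboxylate oxygens")
        cents.append(np.mean(np.array(ox, dtype=float), axis=0))
    cents = np.array(cents, dtype=float).reshape(-1, 3)
    diff = cents[:, None, :] - cents[None, :, :]
    dmat = np.sqrt((diff**2).sum(-1))
    return SiteGeometry(list(residues), cents, dmat)


def ideal_square_distances(side: float) -> np.ndarray:
    """Sorted pairwise-distance multiset of a square: 4 sides + 2 diagonals."""
    return np.array(sorted([side] * 4 + [side * np.sqrt(2.0)] * 2))


def square_match_score(pair_distances: Sequence[float], side: float) -> float:
    """RMS deviation of the sorted six pairwise distances from the ideal
    square multiset (side, side, side, side, side·√2, side·√2)."""
    d = np.sort(np.asarray(pair_distances, dtype=float))
    if d.size != 6:
        raise ValueError("a quadruplet has exactly 6 pairwise distances")
    return float(np.sqrt(np.mean((d - ideal_square_distances(side)) ** 2)))


@dataclass(frozen=True)
class SquareMatch:
    keys: tuple[ResKey, ResKey, ResKey, ResKey]
    score: float


def match_ligand_geometry(geom: SiteGeometry, side: float,
                          tolerance: float = 2.0,
                          prune: bool = True) -> list[SquareMatch]:
    """Rank 4-subsets of centroids against the square charge arrangement.

    Every 4-subset is scored by :func:`square_match_score`; subsets with
    score <= ``tolerance`` are returned in ascending order.  With ``prune``
    (default), subsets containing any pairwise distance outside
    [side - 3·tol, side·√2 + 3·tol] are skipped before scoring — no subset
    that could score within tolerance is lost, since such an outlying
    distance alone contributes more than ``tolerance`` to the RMS.
    """
    n = len(geom.keys)
    if n < 4:
        raise ValueError("need at least 4 centroids")
    if not side > 0:
        raise ValueError("side must be > 0")
    lo = side - 3.0 * tolerance
    hi = side * np.sqrt(2.0) + 3.0 * tolerance
    D = geom.distances
    ok_pair = (D >= lo) & (D <= hi)
    out: list[SquareMatch] = []
    for quad in itertools.combinations(range(n), 4):
        if prune and not all(
            ok_pair[i, j] for i, j in itertools.combinations(quad, 2)
        ):
            continue
        dists = [D[i, j] for i, j in itertools.combinations(quad, 2)]
        score = square_match_score(dists, side)
        if score <= tolerance:
            out.append(SquareMatch(tuple(geom.keys[i] for i in quad), score))
    out.sort(key=lambda m: m.score)
    return out
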