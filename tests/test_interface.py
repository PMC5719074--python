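"""Ionic-contact mapping, homolog transfer and site-geometry matching."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from proteogate import synthetic as syn
from proteogate.interface import (
    IonicContact,
    NEGATIVE_ATOMS,
    POSITIVE_ATOMS,
    SiteGeometry,
    align_and_map,
    build_interface_map,
    find_ionic_contacts,
    match_ligand_geometry,
    site_geometry,
    square_match_score,
    transfer_contacts,
)
from proteogate.structure import Structure, parse_structure
from tests.conftest import PLANTED_PAIRS


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


class TestParsing:
    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(ValueError, match="no atoms"):
            parse_structure(p, format="pdb")

    def test_malformed_record_names_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM      1  CA  GLU A   1      bad_coord\n")
        with pytest.raises(ValueError, match="line 1"):
            parse_structure(p, format="pdb")

    def test_altloc_keeps_first_conformer(self, tmp_path):
        lines = [
            "ATOM      1  CA AGLU A   1       0.000   0.000   0.000  0.50  0.00           C",
            "ATOM      2  CA BGLU A   1       5.000   0.000   0.000  0.50  0.00           C",
            "END",
        ]
        p = tmp_path / "altloc.pdb"
        p.write_text("\n".join(lines) + "\n")
        st_ = parse_structure(p, format="pdb")
        assert len(st_) == 1
        assert st_.atoms[0].xyz[0] == pytest.approx(0.0)

    def test_hydrogens_dropped(self, tmp_path):
        lines = [
            "ATOM      1  CA  GLU A   1       0.000   0.000   0.000  1.00  0.00           C",
            "ATOM      2  HA  GLU A   1       1.000   0.000   0.000  1.00  0.00           H",
            "END",
        ]
        p = tmp_path / "h.pdb"
        p.write_text("\n".join(lines) + "\n")
        assert len(parse_structure(p, format="pdb")) == 1

    def test_unknown_format_rejected(self, toy_complex_path):
        with pytest.raises(ValueError, match="format"):
            parse_structure(toy_complex_path, format="xyz")


# ---------------------------------------------------------------------------
# Contact detection
# ---------------------------------------------------------------------------


def brute_force_contacts(struct: Structure, ga, gb, cutoff):
    """All-pairs oracle for the k-d tree search, residue-pair deduplicated."""
    ga, gb = set(ga), set(gb)
    best = {}
    for a in struct.atoms:
        names = NEGATIVE_ATOMS.get(a.res_name)
        if names is None or a.name not in names:
            continue
        for b in struct.atoms:
            pnames = POSITIVE_ATOMS.get(b.res_name)
            if pnames is None or b.name not in pnames:
                continue
            if not ((a.chain in ga and b.chain in gb) or
                    (a.chain in gb and b.chain in ga)):
                continue
            d = float(np.linalg.norm(np.subtract(a.xyz, b.xyz)))
            if d <= cutoff:
                key = (a.res_key, b.res_key)
                if key not in best or d < best[key]:
                    best[key] = d
    return best


class TestContacts:
    def test_planted_pairs_found_at_their_distances(self, toy_complex):
        contacts = find_ionic_contacts(toy_complex, ["A"], ["B"], cutoff=4.0)
        assert len(contacts) == len(PLANTED_PAIRS)
        got = sorted(round(c.distance, 2) for c in contacts)
        assert got == sorted(d for _, _, d in PLANTED_PAIRS)
        # acidic partner always reported first, sorted by distance
        for c in contacts:
            assert c.negative.res_name in ("ASP", "GLU")
            assert c.positive.res_name in ("LYS", "ARG")
        assert [c.distance for c in contacts] == sorted(c.distance for c in contacts)

    def test_pair_beyond_cutoff_not_reported(self, tmp_path):
        p = tmp_path / "far.pdb"
        p.write_text(syn.gen_toy_complex([("GLU", "LYS", 4.5)], seed=0))
        st_ = parse_structure(p)
        assert find_ionic_contacts(st_, ["A"], ["B"], cutoff=4.0) == []

    def test_decoys_only_give_no_contacts(self, tmp_path):
        p = tmp_path / "decoys.pdb"
        p.write_text(syn.gen_toy_complex([], decoys=10, seed=0))
        st_ = parse_structure(p)
        assert find_ionic_contacts(st_, ["A"], ["B"], cutoff=4.0) == []

    def test_zero_cutoff_empty(self, toy_complex):
        assert find_ionic_contacts(toy_complex, ["A"], ["B"], cutoff=0.0) == []

    def test_overlapping_groups_rejected(self, toy_complex):
        with pytest.raises(ValueError, match="overlap"):
            find_ionic_contacts(toy_complex, ["A"], ["A", "B"])

    def test_matches_all_pairs_oracle(self, toy_complex):
        for cutoff in (2.0, 3.2, 4.0, 8.0):
            fast = find_ionic_contacts(toy_complex, ["A"], ["B"], cutoff=cutoff)
            oracle = brute_force_contacts(toy_complex, ["A"], ["B"], cutoff)
            assert len(fast) == len(oracle)
            for c in fast:
                assert oracle[(c.negative.res_key, c.positive.res_key)] == \
                    pytest.approx(c.distance)

    def test_symmetric_under_group_swap(self, toy_complex):
        fwd = find_ionic_contacts(toy_complex, ["A"], ["B"], cutoff=4.0)
        rev = find_ionic_contacts(toy_complex, ["B"], ["A"], cutoff=4.0)
        as_keys = lambda cs: [(c.negative.res_key, c.positive.res_key) for c in cs]
        assert as_keys(fwd) == as_keys(rev)

    def test_count_monotone_in_cutoff(self, toy_complex):
        counts = [
            len(find_ionic_contacts(toy_complex, ["A"], ["B"], cutoff=c))
            for c in np.linspace(0.5, 10.0, 12)
        ]
        assert counts == sorted(counts)

    def test_groove_grouping_unique_residues(self, toy_complex):
        contacts = find_ionic_contacts(toy_complex, ["A"], ["B"], cutoff=4.0)
        imap = build_interface_map(contacts, groove_by_chain={"A": "a4-a5"})
        assert set(imap.groove_groups) == {"a4-a5"}
        residues = imap.groove_groups["a4-a5"]
        assert len(residues) == len(set(residues))
        assert imap.counts["a4-a5"] == len(residues)


# ---------------------------------------------------------------------------
# Alignment / transfer
# ---------------------------------------------------------------------------


class TestAlignment:
    def test_identity_mapping(self):
        m = align_and_map("MKLVEAGHTRWQ", "MKLVEAGHTRWQ")
        assert all(tgt == tpl and ident for tpl, (tgt, _, _, ident) in m.pairs.items())

    def test_insertion_shifts_downstream_positions(self):
        m = align_and_map("MKLVEAGHTRWQ", "MKLVEPPAGHTRWQ")
        assert m.pairs[3] == (3, "L", "L", True)
        # two-residue insertion after position 5 shifts the tail by +2
        assert m.pairs[8][0] == 10
        assert m.pairs[12][0] == 14

    def test_nonconserved_charge_flagged(self):
        m = align_and_map("AAEAA", "AAQAA")
        tgt, tpl_aa, tgt_aa, identical = m.pairs[3]
        assert (tpl_aa, tgt_aa, identical) == ("E", "Q", False)

    def test_illegal_characters_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            align_and_map("ACDE1", "ACDEF")
        with pytest.raises(ValueError):
            align_and_map("", "ACDEF")


class TestTransfer:
    def _imap(self):
        from proteogate.interface import ContactAtom
        c = IonicContact(
            negative=ContactAtom("A", 3, "", "GLU", "OE1"),
            positive=ContactAtom("B", 2, "", "LYS", "NZ"),
            distance=3.2,
        )
        return build_interface_map([c])

    def test_identity_mapping_preserves_contacts(self):
        imap = self._imap()
        maps = {"A": align_and_map("AAEAA", "AAEAA"),
                "B": align_and_map("AKAAA", "AKAAA")}
        out, report = transfer_contacts(imap, maps)
        assert report.kept == 1 and report.dropped == 0
        assert out.contacts[0].negative.position == 3

    def test_acidic_to_nonacidic_dropped_and_counted(self):
        imap = self._imap()
        maps = {"A": align_and_map("AAEAA", "AAQAA"),
                "B": align_and_map("AKAAA", "AKAAA")}
        out, report = transfer_contacts(imap, maps)
        assert out.contacts == []
        assert report.dropped_nonacidic == 1

    def test_gap_dropped_and_counted(self):
        imap = self._imap()
        maps = {"A": align_and_map("AAEAA", "AAAA"),  # E deleted in target
                "B": align_and_map("AKAAA", "AKAAA")}
        out, report = transfer_contacts(imap, maps)
        assert report.dropped_gap + report.dropped_nonacidic == 1
        assert out.contacts == []

    def test_missing_chain_mapping_raises(self):
        with pytest.raises(KeyError, match="chain"):
            transfer_contacts(self._imap(), {"A": align_and_map("AAEAA", "AAEAA")})


# ---------------------------------------------------------------------------
# Site geometry and square matching
# ---------------------------------------------------------------------------


class TestSiteGeometry:
    def test_two_point_distance(self, tmp_path):
        pairs = [("GLU", "LYS", 3.0)]
        # build a fake structure by hand: two glutamates 17 A apart
        from proteogate.structure import Atom
        atoms = []
        for i, x0 in enumerate((0.0, 17.0)):
            for name, dx in (("OE1", 1.1), ("OE2", -1.1)):
                atoms.append(Atom("A", i + 1, "", "GLU", name, "O", (x0 + dx, 0, 0)))
        st_ = Structure(atoms)
        geom = site_geometry(st_, [("A", 1, ""), ("A", 2, "")])
        assert geom.distances[0, 1] == pytest.approx(17.0)
        assert geom.distances[0, 0] == 0.0
        assert np.allclose(geom.distances, geom.distances.T)

    def test_single_residue_zero_matrix(self, toy_complex):
        key = next(k for k, n in toy_complex.residues().items() if n == "GLU")
        geom = site_geometry(toy_complex, [key])
        assert geom.distances.shape == (1, 1) and geom.distances[0, 0] == 0.0

    def test_matrix_matches_brute_force(self, pseudo_ring):
        keys = [k for k, n in pseudo_ring.residues().items() if n == "GLU"]
        geom = site_geometry(pseudo_ring, keys)
        for i, j in itertools.combinations(range(len(keys)), 2):
            assert geom.distances[i, j] == pytest.approx(
                np.linalg.norm(geom.centroids[i] - geom.centroids[j])
            )

    def test_non_acidic_residue_rejected(self, toy_complex):
        key = next(k for k, n in toy_complex.residues().items() if n == "LYS")
        with pytest.raises(ValueError, match="Asp/Glu"):
            site_geometry(toy_complex, [key])


def _square_geometry(side, jitter=0.0, rng=None):
    pts = np.array([[0, 0, 0], [side, 0, 0], [side, side, 0], [0, side, 0]], float)
    if jitter and rng is not None:
        pts = pts + rng.normal(0, jitter, pts.shape)
    keys = [("A", i + 1, "") for i in range(4)]
    diff = pts[:, None] - pts[None, :]
    return SiteGeometry(keys, pts, np.sqrt((diff**2).sum(-1)))


class TestSquareMatch:
    def test_perfect_square_scores_zero(self):
        geom = _square_geometry(17.0)
        hits = match_ligand_geometry(geom, 17.0, tolerance=1.0)
        assert len(hits) == 1 and hits[0].score == pytest.approx(0.0, abs=1e-9)

    def test_planted_ring_quadruplet_is_top_hit(self, pseudo_ring):
        keys = [k for k, n in pseudo_ring.residues().items() if n == "GLU"]
        geom = site_geometry(pseudo_ring, keys)
        hits = match_ligand_geometry(geom, 17.0, tolerance=2.0)
        assert hits, "planted square not found"
        planted = sorted(k for k in keys if k[1] >= 900)
        assert sorted(hits[0].keys) == planted
        assert hits[0].score < 0.01

    def test_planted_square_rejected_at_wrong_side(self, pseudo_ring):
        """A 17 A square scores far outside tolerance against an 11 A query."""
        keys = [k for k, n in pseudo_ring.residues().items() if n == "GLU"]
        geom = site_geometry(pseudo_ring, keys)
        planted = [k for k in keys if k[1] >= 900]
        idx = [geom.keys.index(k) for k in planted]
        dists = [geom.distances[i, j] for i, j in itertools.combinations(idx, 2)]
        assert square_match_score(dists, 11.0) > 2.0

    def test_pruned_equals_exhaustive(self, pseudo_ring):
        keys = [k for k, n in pseudo_ring.residues().items() if n == "GLU"][:12]
        geom = site_geometry(pseudo_ring, keys)
        for side in (11.0, 17.0, 24.0):
            pruned = match_ligand_geometry(geom, side, tolerance=2.0, prune=True)
            full = match_ligand_geometry(geom, side, tolerance=2.0, prune=False)
            assert [(m.keys, round(m.score, 9)) for m in pruned] == \
                [(m.keys, round(m.score, 9)) for m in full]

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_score_invariant_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        geom = _square_geometry(17.0, jitter=1.0, rng=rng)
        score0 = match_ligand_geometry(geom, 17.0, tolerance=10.0)[0].score
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        pts = geom.centroids @ q.T + rng.normal(0, 50, 3)
        diff = pts[:, None] - pts[None, :]
        geom2 = SiteGeometry(geom.keys, pts, np.sqrt((diff**2).sum(-1)))
        score1 = match_ligand_geometry(geom2, 17.0, tolerance=10.0)[0].score
        assert score1 == pytest.approx(score0, abs=1e-9)

    def test_too_few_centroids_rejected(self):
        geom = _square_geometry(17.0)
        geom = SiteGeometry(geom.keys[:3], geom.centroids[:3], geom.distances[:3, :3])
        with pytest.raises(ValueError, match="4 centroids"):
            match_ligand_geometry(geom, 17.0)
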