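"""Repeat-pair linking, sign tuples, linking matrices and knotoid flags."""

import numpy as np
import pytest

from tautopo.curves import (FilamentModel, PolygonalCurve, annotate_repeats,
                            subcurve)
from tautopo import fingerprints as fp
from tautopo import reference
from tautopo import topology as top
from tautopo.synthetic import make_knot, random_open_curve


def _filament(first=272, n=71, seed=7, planar=False):
    if planar:
        rng = np.random.default_rng(seed)
        steps = rng.normal(size=(n - 1, 2))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        pts = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)]) * 3.8
        curve = PolygonalCurve(np.column_stack([pts, np.zeros(n)]))
    else:
        curve = random_open_curve(n, seed=seed, scale=3.8)
    f = FilamentModel(curve, residue_numbers=np.arange(first, first + n),
                      accession="synthetic", chain_id="A")
    return annotate_repeats(f)


class TestRepeatLinking:
    def test_unresolved_pairs_nd(self):
        f = _filament(first=306, n=73)    # R1/R2 absent, like the AD core
        t = fp.repeat_linking(f)
        assert np.isnan(t[("R1", "R3")])
        assert np.isnan(t[("R2", "R3")])
        assert np.isfinite(t[("R3", "R4")])
        assert np.isfinite(t[("R4", "C")])

    def test_coplanar_filament_all_zero(self):
        t = fp.repeat_linking(_filament(first=272, n=110, planar=True))
        for pair, v in t.values.items():
            if not np.isnan(v):
                assert v == 0.0, pair

    def test_table_symmetric_access(self):
        t = fp.repeat_linking(_filament(first=272, n=110))
        assert t[("R3", "R4")] == t[("R4", "R3")]

    def test_matches_direct_subcurve_linking(self):
        f = _filament(first=272, n=110)
        t = fp.repeat_linking(f)
        direct = top.gauss_linking(subcurve(f, 306, 336), subcurve(f, 337, 368))
        assert t[("R3", "R4")] == pytest.approx(direct, abs=1e-12)

    def test_csv_export(self, tmp_path):
        t = fp.repeat_linking(_filament())
        t.to_csv(tmp_path / "repeats.csv")
        text = (tmp_path / "repeats.csv").read_text()
        assert "R3-R4" in text and "ND" in text


class TestSignTuple:
    def test_all_negative(self):
        t = fp.RepeatLinkTable("x", {p: -0.5 for p in fp.REPEAT_PAIRS})
        assert fp.sign_tuple(t).main == (-1,) * 6

    def test_zero_maps_to_nd(self):
        vals = {p: 1.0 for p in fp.REPEAT_PAIRS}
        vals[("R3", "R4")] = 0.0
        tup = fp.sign_tuple(fp.RepeatLinkTable("x", vals))
        assert tup.main[3] is None

    def test_mirror_flips_every_sign(self):
        f = _filament(first=272, n=110)
        mirrored = FilamentModel(
            f.backbone.transformed(matrix=np.diag([1.0, 1.0, -1.0])),
            residue_numbers=f.residue_numbers, repeats=f.repeats)
        a = fp.sign_tuple(fp.repeat_linking(f))
        b = fp.sign_tuple(fp.repeat_linking(mirrored))
        for x, y in zip(a.main + a.extra, b.main + b.extra):
            assert (x is None and y is None) or x == -y


class TestTupleDistance:
    def test_identical_zero_and_opposite_six(self):
        plus = fp.SignTuple(main=(1,) * 6, extra=(None,) * 3)
        minus = fp.SignTuple(main=(-1,) * 6, extra=(None,) * 3)
        assert fp.tuple_distance(plus, plus) == 0
        assert fp.tuple_distance(plus, minus) == 6

    def test_nd_counts_against_sign(self):
        a = fp.SignTuple(main=(1, None, 1, 1, 1, 1), extra=(None,) * 3)
        b = fp.SignTuple(main=(1, 1, 1, 1, 1, 1), extra=(None,) * 3)
        assert fp.tuple_distance(a, b) == 1

    def test_published_tuple_relations(self):
        """The printed repeat-sign tuples satisfy the reported relations:
        AD/PART/CTE identical, PiD one main-tuple difference from them, PSP
        vs GGT one entry, CBD/AGD at least two entries from PSP and GGT."""
        tup = reference.sign_tuples()
        for fid in ("AD-PHF", "PART", "CTE-I", "CTE-II"):
            assert fp.tuple_distance(tup["AD-SF"], tup[fid]) == 0
        # PiD differs in sigma_lk(R3, C) plus its extra R1 tuple
        assert sum(x != y for x, y in zip(tup["AD-SF"].main, tup["PiD"].main)) == 1
        assert fp.tuple_distance(tup["PSP"], tup["GGT-I"]) == 1
        for a in ("CBD-I", "CBD-II", "AGD-I", "AGD-II"):
            for b in ("PSP", "GGT-I", "GGT-II", "GGT-III"):
                assert fp.tuple_distance(tup[a], tup[b]) >= 2
        assert fp.tuple_distance(tup["CBD-I"], tup["AGD-I"]) <= 1


class TestLinkingMatrix:
    def test_entries_match_direct_linking(self):
        f = _filament(first=1, n=12, seed=5)
        m = fp.linking_matrix(f)
        v = f.backbone.vertices
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(40):
            i, j = sorted(rng.choice(12, 2, replace=False))
            if i >= 2:      # preceding part defined
                direct = top.gauss_linking(PolygonalCurve(v[:i]),
                                           PolygonalCurve(v[i:j + 1]))
                assert m.matrix[i, j] == pytest.approx(direct, abs=1e-10)
                checked += 1
            if j <= 12 - 3:  # following part defined
                direct = top.gauss_linking(PolygonalCurve(v[i:j + 1]),
                                           PolygonalCurve(v[j + 1:]))
                assert m.matrix[j, i] == pytest.approx(direct, abs=1e-10)
                checked += 1
        assert checked > 10

    def test_boundary_entries_nd(self):
        m = fp.linking_matrix(_filament(first=1, n=10, seed=2))
        assert np.isnan(m.matrix[0, 5]) and np.isnan(m.matrix[1, 5])
        assert np.isnan(m.matrix[9, 3]) and np.isnan(m.matrix[8, 3])
        assert np.all(np.isnan(np.diag(m.matrix)))

    def test_bilinearity_over_adjacent_fragments(self):
        """Lk(A, B u C) = Lk(A, B) + Lk(A, C) for consecutive fragments that
        share only their boundary vertex."""
        c = random_open_curve(24, seed=9)
        v = c.vertices
        A = PolygonalCurve(v[:8])
        B = PolygonalCurve(v[9:16])
        C = PolygonalCurve(v[15:])
        BC = PolygonalCurve(v[9:])
        lk = top.gauss_linking(A, BC)
        assert lk == pytest.approx(top.gauss_linking(A, B)
                                   + top.gauss_linking(A, C), abs=1e-10)

    def test_stride(self):
        f = _filament(first=1, n=20, seed=3)
        m = fp.linking_matrix(f, stride=4)
        assert len(m.residues) == 5
        full = fp.linking_matrix(f)
        assert m.matrix[1, 2] == pytest.approx(full.matrix[4, 8], abs=1e-12)

    def test_csv_export(self, tmp_path):
        m = fp.linking_matrix(_filament(first=1, n=8, seed=1))
        m.to_csv(tmp_path / "m.csv")
        assert (tmp_path / "m.csv").read_text().count("\n") == 9


class TestRenderFingerprint:
    def test_zero_matrix_neutral_and_negation_inverts(self, tmp_path):
        res = np.arange(1, 9)
        zero = fp.LinkingMatrix("z", res, np.zeros((8, 8)))
        nzero = fp.LinkingMatrix("z", res, -np.zeros((8, 8)))
        a = fp.render_fingerprint(zero, tmp_path / "a.png")
        b = fp.render_fingerprint(nzero, tmp_path / "b.png")
        assert a.read_bytes() == b.read_bytes()   # 0 and -0 identical

        rng = np.random.default_rng(1)
        mat = rng.normal(size=(8, 8))
        m1 = fp.LinkingMatrix("z", res, mat)
        m2 = fp.LinkingMatrix("z", res, -mat)
        c = fp.render_fingerprint(m1, tmp_path / "c.png")
        d = fp.render_fingerprint(m2, tmp_path / "d.png")
        assert c.read_bytes() != d.read_bytes()   # colors invert with sign


class TestKnotoidFlag:
    def test_planar_curve_not_flagged(self):
        th = np.linspace(0, 1.5 * np.pi, 12)
        arc = PolygonalCurve(np.column_stack([np.cos(th), np.sin(th),
                                              np.zeros_like(th)]))
        flag = fp.knotoid_flag(arc, n_projections=150, seed=1)
        assert not flag.is_knotoid and flag.fraction == 0.0

    def test_closed_knot_all_projections_qualify(self):
        c = make_knot("5_2")
        flag = fp.knotoid_flag(c, n_projections=150, seed=2)
        assert flag.is_knotoid and flag.fraction == 1.0

    def test_k21_some_projections_qualify(self):
        from tautopo.synthetic import make_k21_knotoid
        flag = fp.knotoid_flag(make_k21_knotoid(), n_projections=400, seed=3)
        assert flag.is_knotoid
        assert 0.0 < flag.fraction < 1.0
        assert len(flag.example_directions) > 0
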