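import math

import numpy as np
import pytest

from lvquant.geometry import (CAVITY, INDEX_NAMES, MYOCARDIUM,
                              DegenerateMaskError)
from lvquant.metrics import (MetricReport, boundary_points, dice_coef,
                             evaluate, hausdorff, mae, pcc, phase_error_rate)


# ---- brute-force oracles (direct definitions, no vectorization) -----------

def brute_dice(a, b):
    inter = sa = sb = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            sa += bool(a[i, j])
            sb += bool(b[i, j])
            inter += bool(a[i, j]) and bool(b[i, j])
    return 1.0 if sa + sb == 0 else 2.0 * inter / (sa + sb)


def brute_boundary(region):
    pts = []
    h, w = region.shape
    for i in range(h):
        for j in range(w):
            if not region[i, j]:
                continue
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or not region[ni, nj]:
                    pts.append((i, j))
                    break
    return pts


def brute_hausdorff(a_pts, b_pts):
    def directed(src, dst):
        worst = 0.0
        for p in src:
            best = min(math.dist(p, q) for q in dst)
            worst = max(worst, best)
        return worst
    return max(directed(a_pts, b_pts), directed(b_pts, a_pts))


def brute_mae(p, t):
    return sum(abs(x - y) for x, y in zip(p, t)) / len(p)


def brute_pcc(p, t):
    n = len(p)
    mp = sum(p) / n
    mt = sum(t) / n
    num = sum((x - mp) * (y - mt) for x, y in zip(p, t))
    den = math.sqrt(sum((x - mp) ** 2 for x in p) * sum((y - mt) ** 2 for y in t))
    return num / den


class TestAgainstBruteForce:
    def test_dice_random_instances(self, rng):
        for _ in range(20):
            a = rng.random((7, 9)) > 0.5
            b = rng.random((7, 9)) > 0.5
            assert dice_coef(a, b) == pytest.approx(brute_dice(a, b), abs=1e-12)

    def test_boundary_random_instances(self, rng):
        for _ in range(20):
            r = rng.random((8, 8)) > 0.4
            got = {tuple(p) for p in boundary_points(r)}
            assert got == set(brute_boundary(r))

    def test_hausdorff_random_instances(self, rng):
        for _ in range(20):
            a = rng.integers(0, 12, (rng.integers(1, 9), 2))
            b = rng.integers(0, 12, (rng.integers(1, 9), 2))
            assert hausdorff(a, b) == pytest.approx(
                brute_hausdorff(a.tolist(), b.tolist()), abs=1e-9)

    def test_mae_pcc_random_instances(self, rng):
        for _ in range(20):
            p = rng.standard_normal(15)
            t = rng.standard_normal(15)
            assert mae(p, t) == pytest.approx(brute_mae(p, t), abs=1e-12)
            assert pcc(p, t) == pytest.approx(brute_pcc(p, t), abs=1e-12)

    def test_phase_error_rate_oracle(self, rng):
        for _ in range(10):
            p = rng.integers(0, 2, 13)
            t = rng.integers(0, 2, 13)
            want = sum(int(x != y) for x, y in zip(p, t)) / 13
            assert phase_error_rate(p, t) == pytest.approx(want, abs=1e-12)


class TestTrivialIdentities:
    def test_self_comparison_perfect(self, rng):
        m = rng.random((10, 10)) > 0.5
        assert dice_coef(m, m) == 1.0
        bp = boundary_points(m | ~m)  # full frame: border pixels only
        assert hausdorff(bp, bp) == 0.0
        x = rng.standard_normal(8)
        assert mae(x, x) == 0.0
        assert pcc(x, 2 * x + 1) == pytest.approx(1.0, abs=1e-12)
        assert pcc(x, -x) == pytest.approx(-1.0, abs=1e-12)
        assert phase_error_rate(np.ones(5), np.ones(5)) == 0.0

    def test_disjoint_dice_zero(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[3, 3] = True
        assert dice_coef(a, b) == 0.0

    def test_empty_vs_empty_dice_one(self):
        z = np.zeros((4, 4), bool)
        assert dice_coef(z, z) == 1.0

    def test_known_hausdorff_value(self):
        assert hausdorff([(0, 0)], [(3, 4)]) == pytest.approx(5.0)


class TestErrors:
    def test_shape_mismatches(self, rng):
        with pytest.raises(ValueError):
            dice_coef(np.zeros((2, 2), bool), np.zeros((3, 3), bool))
        with pytest.raises(ValueError):
            mae([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            phase_error_rate([0], [0, 1])

    def test_hausdorff_empty_raises(self):
        with pytest.raises(DegenerateMaskError):
            hausdorff(np.zeros((0, 2)), [(0, 0)])

    def test_pcc_degenerate(self):
        with pytest.raises(ValueError):
            pcc([1.0], [1.0])
        with pytest.raises(ValueError):
            pcc([1.0, 1.0], [0.0, 1.0])


class TestReport:
    def make_report(self, rng):
        n = 6
        tm = np.zeros((n, 16, 16), dtype=np.uint8)
        tm[:, 4:12, 4:12] = MYOCARDIUM
        tm[:, 6:10, 6:10] = CAVITY
        pm = np.roll(tm, 1, axis=2)
        ti = rng.uniform(0.1, 0.5, (n, 11))
        pi = ti + rng.normal(0, 0.01, ti.shape)
        tp = np.array([0, 1, 1, 1, 0, 0])
        pp = np.array([0, 1, 1, 0, 0, 0])
        return evaluate(pm, tm, pi, ti, pp, tp, spacing=2.0)

    def test_evaluate_fields_complete(self, rng):
        rep = self.make_report(rng)
        assert set(rep.dice) == {"cavity", "myocardium"}
        assert set(rep.mae_norm) == set(INDEX_NAMES)
        assert set(rep.pcc) == set(INDEX_NAMES)
        assert rep.phase_error_rate == pytest.approx(1 / 6)
        assert rep.n_frames == 6
        # physical conversions: areas x H*W*s^2, lengths x H*s
        assert rep.mae_phys["area_cav"] == pytest.approx(
            rep.mae_norm["area_cav"] * 16 * 16 * 4.0)
        assert rep.mae_phys["dim1"] == pytest.approx(rep.mae_norm["dim1"] * 32.0)
        assert rep.hausdorff_mm["cavity"] == pytest.approx(
            rep.hausdorff_px["cavity"] * 2.0)

    def test_perfect_prediction_report(self):
        m = np.zeros((3, 12, 12), dtype=np.uint8)
        m[:, 3:9, 3:9] = MYOCARDIUM
        m[:, 5:7, 5:7] = CAVITY
        idx = np.tile(np.linspace(0.1, 0.5, 11), (3, 1)) \
            + np.arange(3)[:, None] * 0.01
        ph = np.array([0, 1, 0])
        rep = evaluate(m, m, idx, idx, ph, ph)
        assert all(v == 1.0 for v in rep.dice.values())
        assert all(v == 0.0 for v in rep.hausdorff_px.values())
        assert all(v == 0.0 for v in rep.mae_norm.values())
        assert all(v == pytest.approx(1.0) for v in rep.pcc.values())
        assert rep.phase_error_rate == 0.0

    def test_json_and_csv_roundtrip(self, rng, tmp_path):
        rep = self.make_report(rng)
        rep.save_json(tmp_path / "r.json")
        back = MetricReport.load_json(tmp_path / "r.json")
        assert back.to_dict() == rep.to_dict()
        rep.save_csv(tmp_path / "r.csv")
        back = MetricReport.load_csv(tmp_path / "r.csv")
        for g in ("dice", "mae_norm", "pcc"):
            for k, v in getattr(rep, g).items():
                assert getattr(back, g)[k] == pytest.approx(v, rel=1e-9)
        assert back.n_frames == rep.n_frames

    def test_validation_rejects_bad_values(self):
        with pytest.raises(ValueError):
            MetricReport(dice={"cavity": 1.5})
        with pytest.raises(ValueError):
            MetricReport(pcc={"dim1": -2.0})
        with pytest.raises(ValueError):
            MetricReport(phase_error_rate=3.0)

    def test_skip_degenerate_hausdorff(self):
        tm = np.zeros((2, 8, 8), dtype=np.uint8)
        tm[0, 2:6, 2:6] = CAVITY     # frame 1 has no cavity anywhere
        pm = tm.copy()
        with pytest.raises(DegenerateMaskError):
            evaluate(pm, tm, None, None, None, None)
        rep = evaluate(pm, tm, None, None, None, None,
                       skip_degenerate_hausdorff=True)
        assert rep.dice["cavity"] == 1.0
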