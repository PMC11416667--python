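"""Enclave analytics: contacts, partition, entropy, curvature, invasions."""

import numpy as np
import pytest
from scipy import stats
from skimage.draw import disk as draw_disk

from conftest import forest_from_truth
from enclavekit import geometry, synthetic, tracking
from enclavekit.geometry import (contact_graph, enclave_partition,
                                 interenclave_contact_fraction,
                                 interface_curvature, invasion_regions,
                                 phenotype_stats, randomized_entropy_null,
                                 shannon_entropy)
from test_tracking import make_record


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

class TestContacts:
    @pytest.mark.parametrize("gap,expected", [(1.0, True), (2.0, False)])
    def test_gap_against_tolerance(self, gap, expected):
        # parallel rods, boundary-to-boundary distance = gap
        a = make_record((0, 0), label=1)
        b = make_record((0, 1.0 + gap), label=2)   # width 1 -> boundaries gap apart
        g = contact_graph([a, b], {1: 1, 2: 2})
        assert g.has_edge(1, 2) is expected

    def test_single_cell_degree_zero(self):
        g = contact_graph([make_record((0, 0), label=1)], {1: 1})
        assert g.degree[1] == 0

    def test_alternating_line_fraction_one(self):
        # gaps of 0.3 um between consecutive rods (neighbors), 1.6 um between
        # next-nearest (not neighbors): every contact is inter-chain
        recs = [make_record((0, i * 1.3), label=i + 1) for i in range(3)]
        chains = {1: 1, 2: 2, 3: 1}
        g = contact_graph(recs, chains)
        assert interenclave_contact_fraction(g) == 1.0

    def test_single_chain_fraction_zero(self):
        recs = [make_record((0, i * 1.3), label=i + 1) for i in range(3)]
        g = contact_graph(recs, {1: 1, 2: 1, 3: 1})
        assert interenclave_contact_fraction(g) == 0.0

    def test_all_isolated_flagged(self):
        recs = [make_record((0, 0), label=1), make_record((0, 50), label=2)]
        g = contact_graph(recs, {1: 1, 2: 2})
        with pytest.warns(UserWarning):
            assert np.isnan(interenclave_contact_fraction(g))

    def test_demixed_colony_fraction_decreases(self, tracked_25c):
        cfg, frames, truth, forest, records = tracked_25c
        fractions = []
        for f in (len(frames) // 2, len(frames) - 1):
            chains = {lab: rec[2] for lab, rec in truth.frame_table(f).items()}
            g = contact_graph(records[f], chains)
            fractions.append(interenclave_contact_fraction(g))
        assert all(x < 0.5 for x in fractions)
        assert fractions[-1] < fractions[0]


# ---------------------------------------------------------------------------
# enclave partition
# ---------------------------------------------------------------------------

def split_disc_mask(radius_px=60, pad=10):
    """Disc of two half-disc labels split by a vertical diameter."""
    size = 2 * (radius_px + pad)
    mask = np.zeros((size, size), dtype=int)
    rr, cc = draw_disk((size // 2, size // 2), radius_px)
    mask[rr, cc] = np.where(cc < size // 2, 1, 2)
    return mask


class TestEnclavePartition:
    def test_split_disc_closed_forms(self):
        px = 0.1
        r = 6.0                      # um
        part = enclave_partition(split_disc_mask(60), {1: 1, 2: 2}, px)
        # L_interface = (Ps1 + Ps2 - L_colony)/2 = 2r for a diameter split
        assert part.interface_length == pytest.approx(2 * r, rel=0.03)
        assert part.interface_measured == pytest.approx(2 * r, rel=0.03)
        # half-disc centroids at +-4r/(3 pi) -> delta_c = 8r/(3 pi)
        assert part.delta_c == pytest.approx(8 * r / (3 * np.pi), rel=0.03)
        assert part.colony_perimeter == pytest.approx(2 * np.pi * r, rel=0.03)
        for c in (1, 2):
            assert part.areas[c] == pytest.approx(np.pi * r ** 2 / 2, rel=0.03)
            assert part.exposed_fraction[c] == pytest.approx(0.5, abs=0.03)

    def test_formula_matches_measured_on_colony(self, tracked_25c):
        cfg, frames, truth, forest, records = tracked_25c
        f = len(frames) - 1
        chains = {lab: rec[2] for lab, rec in truth.frame_table(f).items()}
        part = enclave_partition(frames[f].mask, chains, cfg.pixel_size)
        assert part.interface_length == pytest.approx(part.interface_measured,
                                                      rel=0.05)
        assert 0.35 < part.areas[1] / part.colony_area < 0.65
        assert 0.35 < part.areas[2] / part.colony_area < 0.65

    def test_missing_chain_raises(self):
        with pytest.raises(ValueError):
            enclave_partition(split_disc_mask(30), {1: 1, 2: 1}, 0.1)

    def test_delta_c_grows_along_trajectory(self, tracked_25c):
        """Centroid separation increases with colony size (demixing trend)."""
        cfg, frames, truth, forest, records = tracked_25c
        ns, dcs = [], []
        for f in range(4, len(frames), 4):
            chains = {lab: rec[2] for lab, rec in truth.frame_table(f).items()}
            part = enclave_partition(frames[f].mask, chains, cfg.pixel_size)
            ns.append(len(frames[f].cells))
            dcs.append(part.delta_c)
        rho, p = stats.spearmanr(ns, dcs)
        assert rho > 0 and p < 0.05


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------

class TestEntropy:
    def test_bounds_and_single_chain(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 30, size=(100, 2))
        ent = shannon_entropy(pts, rng.integers(1, 3, 100))
        assert np.all(ent.per_box_se >= 0)
        assert np.all(ent.per_box_se <= np.log(2) + 1e-12)
        assert shannon_entropy(pts, np.ones(100, int)).mean_se == 0.0

    def test_balanced_boxes_reach_ln2(self):
        # one red and one green at each site: every box has p = 1/2
        base = np.array([[i * 3.0, j * 3.0] for i in range(5) for j in range(5)])
        pts = np.vstack([base, base + 0.1])
        labels = np.r_[np.ones(len(base), int), np.full(len(base), 2)]
        ent = shannon_entropy(pts, labels)
        assert ent.mean_se == pytest.approx(np.log(2), abs=1e-9)

    def test_zero_iff_every_box_single_chain(self):
        pts = np.array([[0.0, 0.0], [20.0, 0.0]])
        ent = shannon_entropy(pts, np.array([1, 2]))
        assert ent.mean_se == 0.0           # far apart: no mixed box

    def test_demixed_below_random(self):
        demixed = synthetic.make_two_color_pattern(200, "demixed", seed=5)
        ent_d = shannon_entropy(demixed.centroids, demixed.chains)
        rng = np.random.default_rng(6)
        shuffled = rng.permutation(demixed.chains)
        ent_r = shannon_entropy(demixed.centroids, shuffled)
        assert ent_d.mean_se < ent_r.mean_se

    def test_null_mean_converges(self):
        frame = synthetic.make_two_color_pattern(128, "demixed", seed=8)
        small = randomized_entropy_null(frame.centroids, frame.chains,
                                        iterations=1000, seed=1)
        big = randomized_entropy_null(frame.centroids, frame.chains,
                                      iterations=20_000, seed=2)
        assert small.mean == pytest.approx(big.mean, rel=0.02)

    def test_observed_demixed_below_first_percentile(self, colony_25c):
        cfg, frames, truth = colony_25c
        f = frames[-1]
        null = randomized_entropy_null(f.centroids, f.chains,
                                       iterations=1000, seed=0)
        assert null.percentile_of_observed < 1.0


# ---------------------------------------------------------------------------
# curvature and invasions
# ---------------------------------------------------------------------------

def finger_polyline(width=2.0, depth=6.0, x0=9.0, total=20.0, step=0.1):
    """Straight interface with one rectangular finger at [x0, x0+width]."""
    verts = np.array([[0, 0], [x0, 0], [x0, depth], [x0 + width, depth],
                      [x0 + width, 0], [total, 0]], float)
    out = []
    for a, b in zip(verts[:-1], verts[1:]):
        n = int(np.linalg.norm(b - a) / step) + 2
        out.append(np.linspace(a, b, n)[:-1])
    out.append(verts[-1:])
    return np.vstack(out)


class TestCurvature:
    def test_analytic_circle(self):
        th = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        circ = np.column_stack([5 * np.cos(th), 5 * np.sin(th)])
        geom = interface_curvature(np.vstack([circ, circ[:1]]), threshold=10)
        assert np.all(np.abs(geom.kappa_abs / 0.2 - 1) < 0.02)

    def test_rasterized_circle(self):
        px = 0.1
        mask = np.zeros((140, 140), dtype=int)
        rr, cc = draw_disk((70, 70), 50)
        mask[rr, cc] = 1
        ((poly, _, _),) = tracking.colony_boundary(mask, px)
        geom = interface_curvature(np.asarray(poly.exterior.coords), threshold=10)
        assert geom.kappa_abs.mean() == pytest.approx(0.2, rel=0.02)

    def test_straight_segment_zero(self):
        line = np.column_stack([np.linspace(0, 20, 200), np.zeros(200)])
        geom = interface_curvature(line, threshold=10)
        assert geom.kappa_abs.max() < 1e-9

    def test_sine_crest(self):
        a, k = 2.0, 0.3
        x = np.arange(0, 4 * np.pi / k, 0.1)
        geom = interface_curvature(np.column_stack([x, a * np.sin(k * x)]),
                                   threshold=10)
        crest = geom.kappa_abs[10:-10].max()
        assert crest == pytest.approx(a * k ** 2, rel=0.05)

    def test_sign_follows_reference_side(self):
        # open semicircular arc: positive when bending toward the reference
        th = np.linspace(0.1, np.pi - 0.1, 200)
        arc = np.column_stack([5 * np.cos(th), 5 * np.sin(th)])
        toward = interface_curvature(arc, threshold=10, ref_point=(0.0, 0.0))
        away = interface_curvature(arc, threshold=10, ref_point=(0.0, 20.0))
        assert np.median(toward.kappa_signed) > 0
        assert np.median(away.kappa_signed) < 0

    def test_too_short_polyline_raises(self):
        with pytest.raises(ValueError):
            interface_curvature(np.zeros((3, 2)))


class TestInvasions:
    def test_rectangular_finger(self):
        geom = interface_curvature(finger_polyline(), threshold=0.5)
        regions = invasion_regions(geom)
        assert len(regions) == 1
        assert regions[0].mean_width == pytest.approx(2.0, rel=0.1)
        assert regions[0].area == pytest.approx(12.0, rel=0.1)

    def test_straight_interface_no_regions(self):
        line = np.column_stack([np.linspace(0, 20, 200), np.zeros(200)])
        geom = interface_curvature(line, threshold=0.5)
        assert invasion_regions(geom) == []

    def test_two_fingers_disjoint(self):
        verts = np.array([[0, 0], [5, 0], [5, 6], [7, 6], [7, 0],
                          [13, 0], [13, 5], [16, 5], [16, 0], [22, 0]], float)
        out = []
        for a, b in zip(verts[:-1], verts[1:]):
            n = int(np.linalg.norm(b - a) / 0.1) + 2
            out.append(np.linspace(a, b, n)[:-1])
        poly = np.vstack(out + [verts[-1:]])
        geom = interface_curvature(poly, threshold=0.5)
        regions = invasion_regions(geom)
        assert len(regions) == 2
        areas = sorted(r.area for r in regions)
        assert areas[0] == pytest.approx(12.0, rel=0.1)   # 2 x 6
        assert areas[1] == pytest.approx(15.0, rel=0.1)   # 3 x 5


# ---------------------------------------------------------------------------
# phenotype statistics
# ---------------------------------------------------------------------------

class TestPhenotypes:
    def test_uniform_elongation_rate_recovered(self):
        g = np.log(2) / 48.0
        cfg = synthetic.GeneratorConfig(n_target=32, seed=3, elongation=g)
        frames, truth = synthetic.grow_rod_colony(cfg)
        records = [tracking.extract_features(f.mask, cfg.pixel_size, i)
                   for i, f in enumerate(frames)]
        forest = forest_from_truth(truth)
        stats_ = phenotype_stats(forest, records,
                                 frame_interval=cfg.frame_interval)
        for chain in ("chain1", "chain2"):
            assert stats_.elongation_rates[chain] == pytest.approx(g, rel=0.05)

    def test_equal_lengths_zero_noise(self):
        recs = [[make_record((0, 0), label=1), make_record((5, 0), label=2)]]
        forest = tracking.build_progeny_chains(recs)
        out = phenotype_stats(forest, recs)
        colony = out.per_frame[out.per_frame.group == "colony"]
        assert colony.length_noise.iloc[0] == 0.0

    def test_chains_track_colony_mean(self, tracked_25c):
        cfg, frames, truth, forest, records = tracked_25c
        out = phenotype_stats(forest, records, cfg.frame_interval)
        last = out.per_frame[out.per_frame.frame == len(frames) - 1]
        colony_mean = float(last[last.group == "colony"].mean_length.iloc[0])
        for chain in ("chain1", "chain2"):
            m = float(last[last.group == chain].mean_length.iloc[0])
            assert abs(m - colony_mean) / colony_mean < 0.15
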