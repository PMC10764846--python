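import numpy as np
import pytest

from collatil import til_architecture as ta
from collatil.io_core import NucleusRecord, TileBundle


def nuc(x, y, til=False, comp="neither", front=False):
    return NucleusRecord(x=x, y=y, is_til=til, compartment=comp,
                         in_invasive_front=front)


def brute_force_components(points, radius):
    """Union-find over all O(n^2) pairs; reference for the KD-tree path."""
    parent = list(range(len(points)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            if np.hypot(*(np.array(points[i]) - points[j])) <= radius:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(points)):
        groups.setdefault(find(i), set()).add(i)
    return sorted(frozenset(g) for g in groups.values())


def shoelace(vertices):
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestCompartments:
    def _geometry(self, size=60, split=30, band_um=5.0, mpp=1.0):
        epi = np.zeros((size, size), bool)
        epi[:, :split] = True
        stroma = ~epi
        return ta.CompartmentGeometry(
            epi, stroma,
            ta.invasive_front_mask(epi, stroma, band_um, mpp), band_um)

    def test_mask_membership_assignment(self):
        g = self._geometry()
        nuclei = [nuc(10, 10), nuc(45, 10, til=True)]
        ta.assign_compartments(nuclei, g)
        assert nuclei[0].compartment == "epithelium"
        assert nuclei[1].compartment == "stroma"

    def test_no_epithelium_means_no_front(self):
        size = 40
        stroma = np.ones((size, size), bool)
        front = ta.invasive_front_mask(np.zeros((size, size), bool), stroma, 100, 0.25)
        assert not front.any()

    def test_out_of_raster_nucleus_rejected(self):
        g = self._geometry()
        with pytest.raises(ValueError, match="nucleus 0"):
            ta.assign_compartments([nuc(999, 10)], g)

    def test_front_band_matches_distance_transform_oracle(self):
        """Band membership on a toy mask equals an exact per-pixel check of
        the distance to the nearest boundary pixel."""
        rng = np.random.default_rng(0)
        epi = np.zeros((200, 200), bool)
        epi[40:120, 30:150] = True
        epi[rng.integers(0, 200, 30), rng.integers(0, 200, 30)] = True
        stroma = ~epi
        band_px = 12.0
        front = ta.invasive_front_mask(epi, stroma, band_px, 1.0)
        from scipy import ndimage
        touch = ((ndimage.binary_dilation(epi) & stroma)
                 | (ndimage.binary_dilation(stroma) & epi))
        by, bx = np.nonzero(touch)
        yy, xx = np.mgrid[0:200, 0:200]
        d2 = ((yy[..., None] - by) ** 2 + (xx[..., None] - bx) ** 2).min(axis=-1)
        oracle = (np.sqrt(d2) <= band_px) & (epi | stroma)
        assert np.array_equal(front, oracle)

    def test_front_subset_of_tissue(self):
        g = self._geometry()
        assert not (g.invasive_front_mask & ~(g.epithelium_mask | g.stroma_mask)).any()

    def test_densities_count_per_class(self):
        g = self._geometry(size=60, split=30, mpp=1000.0)  # 1 px = 1 mm
        nuclei = [nuc(5, 5, til=True), nuc(6, 6), nuc(40, 5, til=True), nuc(41, 6)]
        ta.assign_compartments(nuclei, g)
        d = ta.density_per_class(nuclei, g, microns_per_pixel=1000.0)
        area_epi = 60 * 30  # mm^2 at this scale
        assert d["epi_til"] == pytest.approx(1 / area_epi)
        assert d["str_nontil"] == pytest.approx(1 / area_epi)

    def test_empty_compartment_density_is_missing(self):
        size = 20
        g = ta.CompartmentGeometry(np.zeros((size, size), bool),
                                   np.ones((size, size), bool),
                                   np.zeros((size, size), bool))
        d = ta.density_per_class([], g, 0.25)
        assert np.isnan(d["epi_til"]) and d["str_til"] == 0.0


class TestClusters:
    def test_triangle_forms_one_cluster_with_area(self):
        nuclei = [nuc(0, 0, comp="stroma"), nuc(10, 0, comp="stroma"),
                  nuc(0, 10, comp="stroma")]
        (c,) = ta.build_clusters(nuclei, [0, 1, 2], "str_nontil", 20, 1.0)
        assert len(c) == 3 and c.area == pytest.approx(50.0)

    def test_distant_nuclei_stay_singletons(self):
        nuclei = [nuc(0, 0), nuc(500, 0)]
        clusters = ta.build_clusters(nuclei, [0, 1], "str_til", 20, 1.0)
        assert len(clusters) == 2 and all(c.area == 0 for c in clusters)

    def test_collinear_cluster_has_zero_area(self):
        nuclei = [nuc(0, 0), nuc(5, 0), nuc(10, 0)]
        (c,) = ta.build_clusters(nuclei, [0, 1, 2], "epi_til", 20, 1.0)
        assert len(c) == 3 and c.area == 0.0

    @pytest.mark.parametrize("n,seed", [(100, 0), (500, 1)])
    def test_components_match_union_find_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 300, (n, 2))
        nuclei = [nuc(x, y) for x, y in pts]
        radius = 15.0
        clusters = ta.build_clusters(nuclei, list(range(n)), "str_til", radius, 1.0)
        got = sorted(frozenset(c.member_indices) for c in clusters)
        assert got == brute_force_components([tuple(p) for p in pts], radius)

    def test_partition_conserves_membership(self):
        rng = np.random.default_rng(2)
        nuclei = [nuc(x, y) for x, y in rng.uniform(0, 200, (120, 2))]
        clusters = ta.build_clusters(nuclei, list(range(120)), "epi_nontil", 10, 1.0)
        members = sorted(i for c in clusters for i in c.member_indices)
        assert members == list(range(120))

    def test_hull_area_matches_shoelace(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 50, (40, 2))
        nuclei = [nuc(x, y) for x, y in pts]
        (c,) = ta.build_clusters(nuclei, list(range(40)), "str_til", 100, 1.0)
        assert c.area == pytest.approx(shoelace(c.hull), abs=1e-9)


class TestFeatures:
    def test_ratio_nontil_to_surrounding_tils_hand_fixture(self):
        # 4 epithelial non-TILs; 2 TILs each within 20 um (80 px) of one
        nuclei = ([nuc(100 * i, 0, comp="epithelium") for i in range(4)]
                  + [nuc(10, 10, til=True, comp="epithelium"),
                     nuc(110, 10, til=True, comp="stroma"),
                     nuc(0, 500, til=True, comp="stroma")])  # far away
        v = ta.feature_ratio_nontil_to_surrounding_tils(nuclei, 20, 0.25)
        assert v == pytest.approx(4 / 2)

    def test_ratio_guard_without_nearby_tils(self):
        nuclei = [nuc(0, 0, comp="epithelium"), nuc(10, 0, comp="epithelium")]
        assert ta.feature_ratio_nontil_to_surrounding_tils(nuclei) == 2.0

    def test_ratio_zero_without_nontils(self):
        assert ta.feature_ratio_nontil_to_surrounding_tils(
            [nuc(0, 0, til=True, comp="epithelium")]) == 0.0

    def _clusters(self, coords, label, nuclei, offset=0, radius=5):
        idx = list(range(offset, offset + len(coords)))
        for x, y in coords:
            nuclei.append(nuc(x, y, til=label.endswith("_til"), comp="epithelium"))
        return ta.build_clusters(nuclei, idx, label, radius, 1.0)

    def test_til_clusters_near_nontil_cluster(self):
        nuclei = []
        nontil = self._clusters([(0, 0)], "epi_nontil", nuclei)
        til = self._clusters([(3, 0), (50, 0), (200, 0)], "epi_til", nuclei, offset=1)
        v = ta.feature_til_clusters_near_nontil_cluster(til, nontil, nuclei,
                                                        epsilon_um=60, microns_per_pixel=1.0)
        assert v == 2.0  # clusters at 3 and 50 px within 60 px; 200 px is not

    def test_no_nontil_clusters_gives_zero(self):
        assert ta.feature_til_clusters_near_nontil_cluster([], [], []) == 0.0

    def test_presence_pct_one_isolated_of_three(self):
        nuclei = [nuc(0, 0), nuc(10, 0), nuc(500, 0)]
        clusters = ta.build_clusters(nuclei, [0, 1, 2], "str_nontil", 5, 1.0)
        v = ta.feature_presence_pct_nontil_near_nontil(clusters, nuclei,
                                                       epsilon_um=20, microns_per_pixel=1.0)
        assert v == pytest.approx(2 / 3)

    def test_presence_pct_single_cluster_is_zero(self):
        nuclei = [nuc(0, 0)]
        clusters = ta.build_clusters(nuclei, [0], "str_nontil", 5, 1.0)
        assert ta.feature_presence_pct_nontil_near_nontil(clusters, nuclei) == 0.0

    def test_intersected_area_disjoint_and_identical(self):
        tri = [(0, 0), (10, 0), (0, 10)]
        far = [(100, 100), (110, 100), (100, 110)]
        nuclei = []
        a = self._clusters(tri, "epi_til", nuclei, radius=20)
        b = self._clusters(tri, "epi_nontil", nuclei, offset=3, radius=20)
        c = self._clusters(far, "epi_nontil", nuclei, offset=6, radius=20)
        for cl in a + b + c:
            cl.in_invasive_front = True
        assert ta.feature_intersected_area(a, c) == pytest.approx(0.0)
        assert ta.feature_intersected_area(a, b) == pytest.approx(50.0)

    def test_intersected_area_overlapping_squares(self):
        sq1 = [(0, 0), (10, 0), (10, 10), (0, 10)]
        sq2 = [(5, 5), (15, 5), (15, 15), (5, 15)]
        nuclei = []
        a = self._clusters(sq1, "epi_til", nuclei, radius=20)
        b = self._clusters(sq2, "epi_nontil", nuclei, offset=4, radius=20)
        for cl in a + b:
            cl.in_invasive_front = True
        assert ta.feature_intersected_area(a, b) == pytest.approx(25.0)

    def test_cluster_area_stats(self):
        clusters = []
        nuclei = []
        for k, side in enumerate([np.sqrt(10), np.sqrt(24), np.sqrt(80)]):
            tri = [(100 * k, 0), (100 * k + side * np.sqrt(2), 0),
                   (100 * k, side * np.sqrt(2))]
            clusters += self._clusters(tri, "str_til", nuclei, offset=3 * k, radius=30)
        areas = sorted(c.area for c in clusters if len(c) >= 3)
        assert ta.feature_cluster_area_stats(clusters, "min") == pytest.approx(areas[0])
        assert ta.feature_cluster_area_stats(clusters, "range") == pytest.approx(
            areas[-1] - areas[0])

    def test_area_stats_missing_without_qualifying_clusters(self):
        nuclei = [nuc(0, 0)]
        clusters = ta.build_clusters(nuclei, [0], "str_til", 5, 1.0)
        assert np.isnan(ta.feature_cluster_area_stats(clusters, "min"))

    def test_til_density(self):
        nuclei = ([nuc(0, i, til=i < 3, comp="stroma", front=True) for i in range(10)]
                  + [nuc(0, 50, til=True, comp="stroma", front=False)])
        assert ta.til_density(nuclei) == pytest.approx(0.3)

    def test_til_density_missing_without_denominator(self):
        assert np.isnan(ta.til_density([nuc(0, 0, comp="epithelium", front=True)]))

    def test_patient_aggregation_is_mean_over_tiles(self):
        tiles = [{"til_ratio_nontil_surr_til_epi": 2.0, "til_density_front": 0.2},
                 {"til_ratio_nontil_surr_til_epi": 4.0,
                  "til_density_front": float("nan")}]
        out = ta.patient_til_features(tiles)
        assert out["til_ratio_nontil_surr_til_epi"] == pytest.approx(3.0)
        assert out["til_density_front"] == pytest.approx(0.2)
        assert np.isnan(out["til_intersect_area_front"])


class TestScalingConsistency:
    def test_scale_invariance_of_counts_and_quadratic_areas(self):
        """Scaling coordinates and radii by s preserves counts/ratios and
        scales areas by s^2."""
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 200, (80, 2))
        til_flags = rng.random(80) < 0.4
        s = 3.0
        results = {}
        for scale in (1.0, s):
            nuclei = [nuc(x * scale, y * scale, til=bool(t), comp="epithelium")
                      for (x, y), t in zip(pts, til_flags)]
            mpp = 1.0 / scale  # so radii in um scale with the coordinates
            clusters = ta.build_all_clusters(nuclei, link_radius_um=15.0,
                                             microns_per_pixel=mpp)
            ratio = ta.feature_ratio_nontil_to_surrounding_tils(nuclei, 20.0, mpp)
            areas = sorted(c.area for c in clusters["epi_til"] if len(c) >= 3)
            sizes = sorted(len(c) for c in clusters["epi_til"])
            results[scale] = (ratio, sizes, areas)
        assert results[1.0][0] == pytest.approx(results[s][0])
        assert results[1.0][1] == results[s][1]
        np.testing.assert_allclose(np.array(results[s][2]),
                                   s ** 2 * np.array(results[1.0][2]), rtol=1e-9)
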