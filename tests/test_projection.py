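import numpy as np
import pytest
from scipy.stats import pearsonr

from ensemblemap import (
    SecondaryStructure,
    ShapeProfile,
    compare_projections,
    median_deviation_track,
    project_ensemble,
    projection_table,
    render_bubble_chart,
    render_comparison,
    windowed_correlation,
)
from ensemblemap.fixtures import make_shape_pair
from ensemblemap.structures import SHAPE_MISSING

S = SecondaryStructure.from_dotbracket


@pytest.fixture(scope="module")
def toy_map(engine, hairpin):
    """Small map built once for all projection tests."""
    from ensemblemap import build_map

    cmap, _ = build_map(hairpin, engine, n_samples=300, seed=21)
    return cmap


class TestProjection:
    def test_counts_conserved_and_fractions_normalized(self, engine, hairpin,
                                                       toy_map):
        structs = engine.sample_boltzmann(hairpin, 500, seed=33)
        proj = project_ensemble(structs, toy_map)
        assert sum(proj.counts.values()) == 500
        assert sum(proj.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_exact_match_concentrates_on_one_cluster(self, toy_map):
        medoid = toy_map.clusters[0].medoid
        proj = project_ensemble([medoid] * 40, toy_map)
        assert proj.counts[toy_map.clusters[0].cluster_id] == 40
        assert not proj.fallback_log

    def test_unmatched_structure_falls_back_to_nearest_with_low_id_tie(self):
        from ensemblemap.mapping import ConformationalMap
        from ensemblemap.nestedness import StructureCluster

        # two clusters whose vectors are equidistant from the projected one
        n = 12
        va = np.zeros(n, dtype=int); va[0] = 2
        vb = np.zeros(n, dtype=int); vb[0] = 4
        medoid = S("((((....))))")
        clusters = [
            StructureCluster(0, va, [medoid], medoid, 1),
            StructureCluster(1, vb, [medoid], medoid, 1),
        ]
        cmap = ConformationalMap(
            sequence_id="t", sequence="GGGGAAAACCCC", clusters=clusters,
            D=np.array([[0.0, 2.0], [2.0, 0.0]]), coords=np.zeros((2, 2)),
            stress=0.0, provenance=[], params={"min_helix": 1},
        )
        # this structure's vector is [3, 0, ...]: distance 1 to both clusters
        novel = S("((.((...))))")
        proj = project_ensemble([novel], cmap)
        assert proj.counts[0] == 1  # tie broken toward the lower cluster id
        assert proj.fallback_log and proj.fallback_log[0][1] == 0

    def test_length_mismatch_rejected(self, toy_map):
        with pytest.raises(ValueError, match="length"):
            project_ensemble([S("....")], toy_map)

    def test_table_lists_every_cluster(self, engine, hairpin, toy_map):
        structs = engine.sample_boltzmann(hairpin, 100, seed=2)
        table = projection_table(project_ensemble(structs, toy_map))
        assert len(table) == toy_map.n_clusters
        assert table["count"].sum() == 100


class TestComparison:
    def test_identical_projections_have_zero_differences(self, engine,
                                                         hairpin, toy_map):
        structs = engine.sample_boltzmann(hairpin, 200, seed=5)
        proj = project_ensemble(structs, toy_map)
        table, summary = compare_projections(proj, proj)
        assert np.allclose(table["difference"], 0.0)
        assert not summary["dominant_switched"]

    def test_dominant_switch_detected(self, toy_map):
        a = project_ensemble([toy_map.clusters[0].medoid] * 10, toy_map)
        b = project_ensemble([toy_map.clusters[1].medoid] * 10, toy_map)
        table, summary = compare_projections(a, b)
        ca, cb = (toy_map.clusters[0].cluster_id,
                  toy_map.clusters[1].cluster_id)
        diff = dict(zip(table["cluster_id"], table["difference"]))
        assert diff[ca] == pytest.approx(-1.0)
        assert diff[cb] == pytest.approx(1.0)
        assert summary["dominant_switched"]

    def test_charts_are_deterministic_and_stable_space(self, engine, hairpin,
                                                       toy_map, tmp_path):
        structs_a = engine.sample_boltzmann(hairpin, 100, seed=1)
        structs_b = engine.sample_boltzmann(hairpin, 100, seed=9)
        pa = project_ensemble(structs_a, toy_map)
        pb = project_ensemble(structs_b, toy_map)
        before = toy_map.to_json()
        render_bubble_chart(pa, tmp_path / "a.svg")
        render_comparison(pa, pb, tmp_path / "ab.svg")
        assert toy_map.to_json() == before  # projection never mutates the map
        one = render_bubble_chart(pa, tmp_path / "a1.svg")
        two = render_bubble_chart(pa, tmp_path / "a2.svg")
        svg1 = one.read_text()
        svg2 = two.read_text()
        # strip volatile SVG metadata (creation date) before comparing
        strip = lambda t: "\n".join(
            ln for ln in t.splitlines() if "date" not in ln.lower()
        )
        assert strip(svg1) == strip(svg2)


class TestWindowedCorrelation:
    def test_identical_profiles_give_unit_correlation(self, rng):
        p = ShapeProfile("p", rng.exponential(size=120))
        mat = windowed_correlation(p, p, wmin=40, wmax=60, wstep=10)
        assert np.allclose(mat.compressed(), 1.0)

    def test_negated_profiles_give_minus_one(self, rng):
        vals = rng.exponential(size=120)
        mat = windowed_correlation(
            ShapeProfile("a", vals), ShapeProfile("b", -vals),
            wmin=40, wmax=50, wstep=5,
        )
        assert np.allclose(mat.compressed(), -1.0)

    def test_default_grid_has_21_window_sizes(self, rng):
        vals = rng.exponential(size=150)
        mat = windowed_correlation(ShapeProfile("a", vals),
                                   ShapeProfile("b", vals))
        assert mat.shape[0] == 21

    def test_matches_naive_pearson_oracle(self, rng):
        a = rng.exponential(size=90)
        b = rng.exponential(size=90)
        mat = windowed_correlation(ShapeProfile("a", a), ShapeProfile("b", b),
                                   wmin=40, wmax=50, wstep=5)
        for k, w in enumerate([40, 45, 50]):
            for s in range(90 - w + 1):
                expected = pearsonr(a[s:s + w], b[s:s + w]).statistic
                assert mat[k, s] == pytest.approx(expected, abs=1e-12)

    def test_low_coverage_windows_masked(self, rng):
        a = rng.exponential(size=100)
        b = a.copy()
        a[10:40] = SHAPE_MISSING  # 30 missing of any 40-window covering them
        mat = windowed_correlation(ShapeProfile("a", a), ShapeProfile("b", b),
                                   wmin=40, wmax=40, wstep=5)
        assert mat.mask[0, 10]
        assert not mat.mask[0, 55]

    def test_divergent_block_depresses_local_correlation(self):
        p1, p2 = make_shape_pair(seed=4, length=200, divergent_block=(20, 30))
        mat = windowed_correlation(p1, p2, wmin=40, wmax=40, wstep=5)
        covering = mat[0, :25].compressed()
        outside = mat[0, 60:150].compressed()
        assert covering.mean() < outside.mean()
        assert outside.mean() > 0.9

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            windowed_correlation(ShapeProfile("a", np.zeros(50)),
                                 ShapeProfile("b", np.zeros(60)))


class TestMedianDeviationTrack:
    def test_constant_profile_gives_zero_everywhere(self):
        p = ShapeProfile("c", np.full(80, 0.7))
        track = median_deviation_track(p)
        assert np.allclose(track.compressed(), 0.0)

    def test_elevated_block_raises_only_overlapping_windows(self):
        vals = np.full(150, 1.0)
        vals[60:110] = 2.0
        track = median_deviation_track(ShapeProfile("p", vals), window=50)
        # windows disjoint from the block: starts 0..10 and 110..
        assert np.allclose(track[:11].compressed(), 0.0)
        assert track[60] == pytest.approx(1.0)  # window 60..109 fully elevated
        assert all(track[11:60] > 0.0)

    def test_sign_convention_positive_means_less_structured(self, rng):
        vals = rng.exponential(size=100)
        vals[:50] += 5.0  # strongly reactive = flexible = unstructured
        track = median_deviation_track(ShapeProfile("p", vals), window=50)
        assert track[0] > 0

    def test_window_longer_than_profile_rejected(self):
        with pytest.raises(ValueError):
            median_deviation_track(ShapeProfile("p", np.zeros(30)), window=50)

    def test_missing_entries_excluded(self):
        vals = np.full(60, 1.0)
        vals[0] = SHAPE_MISSING
        track = median_deviation_track(ShapeProfile("p", vals), window=50)
        assert track[0] == pytest.approx(0.0)
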