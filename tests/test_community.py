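"""Synthetic community generator: profiles, library structure, ground truth."""

import numpy as np
import pytest

from codonbin import (
    CommunitySpec,
    STOP_CODONS,
    build_profile,
    concentration_for_distance,
    euclidean_distance,
    generate_gc_temperature_points,
    generate_library,
    sample_species_profiles,
)
from codonbin.codons import codons_of
from codonbin.community import geometric_abundance


def test_concentration_maps_distance_to_dirichlet_spread():
    """Higher concentration -> flatter profiles -> smaller pairwise distances."""
    rng = np.random.default_rng(0)
    for d_target in (0.05, 0.15):
        a = concentration_for_distance(d_target)
        draws = rng.dirichlet(np.full(61, a), size=40)
        dists = [
            np.linalg.norm(draws[i] - draws[j])
            for i in range(40)
            for j in range(i + 1, 40)
        ]
        assert np.mean(dists) == pytest.approx(d_target, rel=0.25)


def test_profile_sampling_respects_distance_window():
    spec = CommunitySpec(
        n_species=10, clones_per_species=[1] * 10,
        target_distance_window=(0.04, 0.06), seed=3,
    )
    profs = sample_species_profiles(spec)
    for i in range(10):
        for j in range(i + 1, 10):
            d = euclidean_distance(profs[i], profs[j])
            assert 0.04 <= d <= 0.06


def test_profile_sampling_is_seed_deterministic():
    spec = CommunitySpec(n_species=4, clones_per_species=[1] * 4, seed=5)
    a = sample_species_profiles(spec)
    b = sample_species_profiles(spec)
    assert all(np.array_equal(x.counts, y.counts) for x, y in zip(a, b))


def test_unsatisfiable_window_raises_with_diagnostics():
    # concentration 50 keeps all draws within ~0.03 of uniform, so a
    # [0.3, 0.35] pairwise window can never be satisfied
    spec = CommunitySpec(
        n_species=3, clones_per_species=[1] * 3,
        dirichlet_concentration=50.0, target_distance_window=(0.3, 0.35), seed=1,
    )
    with pytest.raises(RuntimeError, match="window"):
        sample_species_profiles(spec, max_tries=200)


def test_geometric_abundance_has_dominant_group():
    counts = geometric_abundance(20)
    assert counts[0] == 34
    assert counts == sorted(counts, reverse=True)
    assert min(counts) >= 1


class TestLibrary:
    def test_truth_table_complete_and_unique(self, small_library):
        truth = small_library.truth
        assert truth["id"].is_unique
        clone_ids = {r.clone_id for r in small_library.clone_records}
        read_ids = {r.clone_id for r in small_library.end_reads}
        assert set(truth.query("kind=='clone'")["id"]) == clone_ids
        assert set(truth.query("kind=='end_read'")["id"]) == read_ids
        # two end reads per clone, mate-linked
        assert len(read_ids) == 2 * len(clone_ids)

    def test_generated_cds_have_no_internal_stops(self, small_library):
        for rec in small_library.clone_records[:5]:
            for cds in rec.cds_sequences:
                internal = codons_of(cds)[1:-1]
                assert not set(internal) & set(STOP_CODONS)
                assert cds[-3:] in STOP_CODONS and len(cds) % 3 == 0

    def test_gff3_coordinates_reproduce_cds_strings(self, small_library, tmp_path):
        """Extracting by coordinates from the written FASTA+GFF3 recovers the
        generated CDS strings exactly (strand-aware round-trip)."""
        from codonbin.io import read_cds

        paths = small_library.write(tmp_path)
        recovered = {r.clone_id: r.cds_sequences for r in read_cds(paths["clones_fasta"], paths["clones_gff3"])}
        for rec in small_library.clone_records:
            assert recovered[rec.clone_id] == rec.cds_sequences

    def test_zero_spacer_concatenation_conserves_length(self):
        spec = CommunitySpec(
            n_species=2, clones_per_species=[1, 1], codons_per_clone=(600, 900),
            spacer_length=0, seed=8,
        )
        lib = generate_library(spec)
        for rec in lib.clone_records:
            assert len(lib.clone_sequences[rec.clone_id]) == sum(map(len, rec.cds_sequences))

    def test_clone_codon_budget_in_requested_range(self, small_library):
        lo, hi = small_library.spec.codons_per_clone
        for rec in small_library.clone_records:
            p = build_profile(rec)
            assert lo - 5 <= p.total_codons <= hi

    def test_clone_profiles_recover_species_assignment(self, small_library):
        """Clustering regenerated profiles at 0.04 matches the truth exactly
        when species are >= 0.08 apart and clones are deep."""
        from codonbin import CodonUsageClusterer

        profiles = [build_profile(r) for r in small_library.clone_records]
        est = CodonUsageClusterer(threshold=0.04).fit(profiles)
        truth = small_library.truth.query("kind=='clone'").set_index("id")["species"]
        pred_parts = {
            frozenset(m) for m in est.grouping_.groups.values()
        }
        true_parts = {
            frozenset(truth.index[truth == s]) for s in truth.unique()
        }
        assert pred_parts == true_parts


def test_gc_temperature_points_exact_without_noise():
    from codonbin import fit_points

    pts = generate_gc_temperature_points(n=10, slope=3.0, intercept=-101.0, noise_sd=0.0, seed=2)
    model = fit_points(pts)
    assert model.slope_ == pytest.approx(3.0, abs=1e-9)
    assert model.intercept_ == pytest.approx(-101.0, abs=1e-6)
    assert model.r_squared_ == pytest.approx(1.0, abs=1e-12)


def test_gc_temperature_points_noisy_recovery_within_three_se():
    from codonbin import fit_points

    pts = generate_gc_temperature_points(n=10, slope=3.0, intercept=-101.0, noise_sd=2.0, seed=4)
    model = fit_points(pts)
    x = pts["gc_percent"].to_numpy()
    se = 2.0 / np.sqrt(np.sum((x - x.mean()) ** 2))
    assert abs(model.slope_ - 3.0) < 3 * se


def test_gc_temperature_points_deterministic():
    a = generate_gc_temperature_points(seed=6)
    b = generate_gc_temperature_points(seed=6)
    assert a.equals(b)
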