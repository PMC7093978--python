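import numpy as np
import pytest

import pamkit as pk
from pamkit.pam import classify_pam, iupac_match
from pamkit.simulate import IndelSpec, PlantedSite, SimulationConfig, SubstrateLayout


class TestRateProfiles:
    def test_stringent_values(self):
        prof = pk.make_rate_profile("stringent", k_max=0.5, seed=1)
        assert prof.k_by_pam["TTTA"] == 0.5
        assert prof.k_by_pam["CTTA"] == pytest.approx(0.05)
        assert prof.k_by_pam["TCTA"] < 0.05  # near-zero background

    @pytest.mark.parametrize("preset", ["stringent", "permissive", "uniform"])
    def test_vrrt_pams_never_cleaved(self, preset):
        prof = pk.make_rate_profile(preset, k_max=0.5, seed=3)
        assert prof.k_by_pam["AGGT"] == 0.0
        assert all(prof.k_by_pam[p] == 0.0 for p in pk.vrrt_pams())

    def test_uniform_preset(self):
        prof = pk.make_rate_profile("uniform", k_max=0.3, seed=0)
        non_vrrt = [p for p in pk.enumerate_pams(4) if not iupac_match("VRRT", p)]
        assert all(prof.k_by_pam[p] == 0.3 for p in non_vrrt)

    def test_permissive_class_ordering(self):
        prof = pk.make_rate_profile("permissive", k_max=0.5, seed=5)
        k = prof.k_by_pam
        for pam in pk.enumerate_pams(4):
            cls = classify_pam(pam)
            if cls in ("CTTV", "TCTV", "TTCV"):
                assert 0.1 <= k[pam] <= 0.2
            elif cls in ("CCTV", "TCCV", "CCCV"):
                assert k[pam] == pytest.approx(0.05)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            pk.make_rate_profile("lenient", 0.5, 0)


class TestSubstrateLayout:
    def test_geometry_adds_up(self):
        layout = SubstrateLayout()
        assert layout.left_flank + 4 + len(layout.protospacer) + layout.right_flank == 150
        assert len(layout.protospacer) == 23

    def test_read_must_cover_pam_and_anchor(self):
        with pytest.raises(ValueError, match="read_length"):
            SimulationConfig(read_length=40)

    def test_time_grid_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(time_grid=(1.0, 2.0))
        with pytest.raises(ValueError):
            SimulationConfig(time_grid=(0.0, 2.0, 2.0))


class TestDepletionRun:
    def test_truth_frequencies_conserved_and_monotone(self, small_run):
        truth = small_run.truth
        times = sorted(small_run.samples)
        cols = [f"f_t{t:g}" for t in times]
        for col in cols:
            assert truth[col].min() >= 0
            assert truth[col].sum() == pytest.approx(1.0)
        # expected remaining fraction is non-increasing for every PAM
        remaining = truth["f0"].to_numpy()[:, None] * np.exp(
            -np.outer(truth["k"].to_numpy(), times)
        )
        assert (np.diff(remaining, axis=1) <= 1e-15).all()
        depleting = truth["k"] > 0
        assert (np.diff(remaining[depleting.to_numpy()], axis=1) < 0).all()

    def test_truth_passes_through_profile(self, small_run):
        prof = small_run.config.profile
        assert all(
            small_run.truth.loc[p, "k"] == prof.k_by_pam[p]
            for p in small_run.truth.index
        )

    def test_t0_matches_control_composition(self, small_run):
        truth = small_run.truth
        assert np.allclose(truth["f_t0"], truth["f0"])

    def test_tttv_frequencies_decrease_through_time(self, small_run):
        counts = small_run.sampled_counts
        tttv = [p for p in counts.index if classify_pam(p) == "TTTV"]
        times = sorted(small_run.samples)
        freq = counts[[small_run.samples[t].name for t in times]].loc[tttv].sum()
        freq = freq / small_run.config.reads_per_sample
        # strong depletion: early vs late, robust to sampling noise
        assert freq.iloc[-1] < 0.05 * freq.iloc[0]

    def test_seed_determinism_byte_identical(self, tmp_path):
        prof = pk.make_rate_profile("stringent", 0.5, seed=4)
        cfg = pk.SimulationConfig(profile=prof, reads_per_sample=500, seed=4)
        a = pk.simulate_depletion_run(cfg)
        b = pk.simulate_depletion_run(cfg)
        pa = a.control.write_fastq(tmp_path / "a.fastq")
        pb = b.control.write_fastq(tmp_path / "b.fastq")
        assert pa.read_bytes() == pb.read_bytes()
        for t in a.samples:
            assert (a.samples[t].seq == b.samples[t].seq).all()
            assert (a.samples[t].qual == b.samples[t].qual).all()

    def test_reads_contain_pam_and_anchor(self, clean_run):
        layout = clean_run.config.layout
        anchor = clean_run.anchor
        n_rev = 0
        for rid, seq, qual in list(clean_run.control.iter_reads())[:500]:
            assert len(seq) == clean_run.config.read_length == len(qual)
            if anchor not in seq:
                seq = pk.reverse_complement(seq)
                n_rev += 1
            i = seq.index(anchor)
            assert i == layout.pam_start + layout.pam_length
        assert 0 < n_rev < 100  # ~10% reverse-complemented


class TestAmpliconSimulation:
    def test_exact_edited_count(self, amplicon_reference):
        ref, proto = amplicon_reference
        out = pk.simulate_amplicon_reads(ref, proto, 0.3, n_reads=1000, seed=7)
        assert out.n_edited == 300
        assert len(out.reads) == 1000

    def test_all_wildtype_and_all_edited(self, amplicon_reference):
        ref, proto = amplicon_reference
        wt = pk.simulate_amplicon_reads(ref, proto, 0.0, n_reads=50,
                                        error_rate=0.0, seed=1)
        assert wt.n_edited == 0
        assert all(seq == ref for _, seq, _ in wt.reads)
        ed = pk.simulate_amplicon_reads(
            ref, proto, 1.0, IndelSpec(size=4, kind="deletion"),
            n_reads=50, error_rate=0.0, seed=1,
        )
        assert all(len(seq) == len(ref) - 4 for _, seq, _ in ed.reads)

    def test_insertion_lengthens_reads(self, amplicon_reference):
        ref, proto = amplicon_reference
        out = pk.simulate_amplicon_reads(
            ref, proto, 1.0, IndelSpec(size=2, kind="insertion"),
            n_reads=10, error_rate=0.0, seed=3,
        )
        assert all(len(seq) == len(ref) + 2 for _, seq, _ in out.reads)

    def test_indel_outside_reference_rejected(self, amplicon_reference):
        ref, proto = amplicon_reference
        with pytest.raises(ValueError):
            pk.simulate_amplicon_reads(
                ref, proto, 0.5, IndelSpec(size=4, offset=500), n_reads=10
            )


class TestGenomeSimulation:
    def test_planted_site_manifest(self):
        spacer = "A" * 23
        g = pk.simulate_genome(
            10000, [PlantedSite(spacer, "TTTA", "+", 0, position=1234)], seed=1
        )
        row = g.manifest.iloc[0]
        assert (row.start, row.end, row.strand) == (1234, 1234 + 27, "+")
        assert g.sequences["chr1"][1234:1261] == "TTTA" + spacer

    def test_mismatch_count_by_construction(self):
        spacer = "ACGT" * 5 + "ACG"
        g = pk.simulate_genome(5000, [PlantedSite(spacer, "TTTC", "+", 2)], seed=2)
        row = g.manifest.iloc[0]
        planted = g.sequences["chr1"][row.start + 4 : row.end]
        assert sum(a != b for a, b in zip(planted, spacer)) == 2
        assert row.n_mismatches == 2

    def test_degenerate_base_probs(self):
        g = pk.simulate_genome(100, base_probs=(0, 0, 0, 1), seed=0)
        assert g.sequences["chr1"] == "T" * 100

    def test_overlapping_plants_rejected(self):
        spacer = "C" * 23
        with pytest.raises(ValueError, match="overlap"):
            pk.simulate_genome(
                1000,
                [PlantedSite(spacer, "TTTA", "+", 0, position=100),
                 PlantedSite(spacer, "TTTA", "+", 0, position=110)],
                seed=0,
            )
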