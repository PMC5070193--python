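"""Domain scanning, architecture calling, motif diagnostics and logos."""

import math

import numpy as np
import pytest

from tandemaaa.seqio import MultipleAlignment, ProteinSequence
from tandemaaa.domain_scan import (DomainHit, call_architecture, compute_logo,
                                   detect_hbyx, detect_tail_helix_tyr,
                                   extract_motifs, model_family, model_role,
                                   scan_sequence)
from tandemaaa.profile_hmm import sample_background, viterbi
from tandemaaa.seqio import AMINO_ACIDS
from tandemaaa.synthgen import default_motif_annotations


def _protein(ds, family, species=None):
    rows = ds.truth[ds.truth.family == family]
    if species is not None:
        rows = rows[rows.species == species]
    row = rows.iloc[-1]
    seq = next(p for p in ds.proteins if p.id == row.protein_id)
    return seq, row


class TestHbyx:
    @pytest.mark.parametrize("tail,expected", [
        ("AYG", True),    # hydrophobic-Y-any
        ("GYG", False),   # G is not hydrophobic
        ("AFG", False),   # F != Y under the strict default
        ("LYA", True),
        ("AYK", True),
    ])
    def test_rule(self, tail, expected):
        assert detect_hbyx("MKVLT" + tail) is expected

    def test_phe_tolerated_when_configured(self):
        assert detect_hbyx("MKVLTAFG", allow_phe=True) is True

    def test_too_short_is_error(self):
        with pytest.raises(ValueError):
            detect_hbyx("AY")


class TestScan:
    def test_planted_domain_gets_rank1_hit_from_true_model(
            self, small_dataset, small_library):
        seq, row = _protein(small_dataset, "Cdc48")
        d_models = {n: m for n, m in small_library.items()
                    if model_role(n) in ("D1", "D2")}
        hits = scan_sequence(seq, d_models, n_database=100)
        rank1 = [h for h in hits if h.rank == 1 and h.evalue <= 1e-6]
        assert {h.model_name for h in rank1} >= {"Cdc48_D1", "Cdc48_D2"}

    def test_tandem_envelopes_in_coordinate_order(self, small_dataset,
                                                  small_library):
        seq, row = _protein(small_dataset, "Spaf")
        hits = scan_sequence(seq, small_library, n_database=100)
        d1 = next(h for h in hits if h.model_name == "Spaf_D1" and h.rank == 1)
        d2 = next(h for h in hits if h.model_name == "Spaf_D2" and h.rank == 1)
        assert d1.end <= d2.start
        # envelopes track the planted coordinates
        assert abs(d1.start - row.d1_start) <= 15
        assert abs(d2.end - row.d2_end) <= 15

    def test_random_background_passes_soft_bound_rarely(self, small_library):
        rng = np.random.default_rng(9)
        model = small_library["NVL_D1"]
        n_pass = 0
        trials = 100
        for i in range(trials):
            res = "".join(AMINO_ACIDS[k] for k in sample_background(rng, 500))
            seq = ProteinSequence(f"bg{i}", res)
            hits = scan_sequence(seq, {"NVL_D1": model}, n_database=1)
            if any(h.evalue <= 1e-3 for h in hits):
                n_pass += 1
        assert n_pass <= 1   # >= 99 % of trials clean

    def test_group_size_capped_at_max_reported(self, small_dataset,
                                               small_library):
        seq, _ = _protein(small_dataset, "Cdc48")
        hits = scan_sequence(seq, small_library, max_reported=4,
                             n_database=100)
        groups = {}
        for h in hits:
            groups.setdefault((h.rank == 1, h.start // 50), 0)
        ranks = [h.rank for h in hits]
        assert max(ranks) <= 4 and min(ranks) >= 1

    def test_uncalibrated_model_rejected(self, small_dataset, small_library):
        from tandemaaa.profile_hmm import ProfileHMM
        import copy
        m = copy.deepcopy(small_library["Cdc48_D1"])
        m.gumbel_lambda = None
        seq, _ = _protein(small_dataset, "Cdc48")
        with pytest.raises(ValueError, match="not calibrated"):
            scan_sequence(seq, {"x": m})


class TestArchitecture:
    def _arch(self, ds, library, family, species=None):
        seq, row = _protein(ds, family, species)
        hits = scan_sequence(seq, library, n_database=100)
        fam = row.family
        ann = default_motif_annotations(ds, fam.replace("_2", ""), "D1")
        return seq, row, call_architecture(seq, hits, library,
                                           motif_annotations=ann)

    def test_cdc48_like_protein_flags(self, small_dataset, small_library):
        _, _, arch = self._arch(small_dataset, small_library, "Cdc48")
        assert arch.has_tandem_D1D2
        assert arch.has_N_domain
        assert arch.has_tail_helix_tyr
        assert arch.has_hbyx

    def test_nsf_like_lacks_tail_and_hbyx(self, small_dataset, small_library):
        _, _, arch = self._arch(small_dataset, small_library, "NSF")
        assert arch.has_tandem_D1D2 and arch.has_N_domain
        assert not arch.has_tail_helix_tyr
        assert not arch.has_hbyx

    def test_nvl_like_insert_before_terminal_helix(self, small_dataset,
                                                   small_library):
        # the planted NVL-family D1 insert (~50 residues before the
        # terminal helix) shows up as insert states when the segment is
        # aligned to an insert-free homologous model
        from tandemaaa.domain_scan import _insert_length
        from tandemaaa.profile_hmm import build_hmm
        from tandemaaa import pipeline as pl
        seeds = pl.seed_truth_alignments(small_dataset)
        ref = build_hmm(seeds["Cdc48_D1"], "ref")   # insert-free homolog
        vals = []
        for _, row in small_dataset.truth.iterrows():
            if row.family != "NVL":
                continue
            seq = next(p for p in small_dataset.proteins
                       if p.id == row.protein_id)
            path = viterbi(ref, seq.residues[row.d1_start:row.d1_end])
            vals.append(_insert_length(path, ref.L - 60, ref.L))
        assert np.median(vals) == pytest.approx(50, abs=15)

    def test_single_domain_is_not_tandem(self, small_dataset, small_library):
        seq, row = _protein(small_dataset, "Cdc48")
        # truncate to the D2 region only
        sub = ProteinSequence("d2only", seq.residues[row.d2_start:row.d2_end])
        hits = scan_sequence(sub, small_library, n_database=100)
        arch = call_architecture(sub, hits, small_library)
        assert not arch.has_tandem_D1D2

    def test_calls_sorted_and_disjoint(self, small_dataset, small_library):
        _, _, arch = self._arch(small_dataset, small_library, "Pex1")
        starts = [h.start for _, h in arch.calls]
        assert starts == sorted(starts)
        for (l1, h1), (l2, h2) in zip(arch.calls, arch.calls[1:]):
            assert h1.overlap_frac(h2) <= 0.1


class TestTailHelix:
    def test_intact_tail_detected_and_deleted_tail_not(self, small_dataset,
                                                       small_library):
        seq, row = _protein(small_dataset, "Spaf")
        hits = scan_sequence(seq, small_library, n_database=100)
        d2 = next(h for h in hits if h.model_name == "Spaf_D2" and h.rank == 1)
        assert detect_tail_helix_tyr(seq, d2, small_library) is True
        truncated = ProteinSequence("nsfish", seq.residues[: row.d2_end])
        assert detect_tail_helix_tyr(truncated, d2, small_library) is False

    def test_sequence_ending_inside_envelope_is_false(self, small_dataset,
                                                      small_library):
        seq, row = _protein(small_dataset, "Spaf")
        hits = scan_sequence(seq, small_library, n_database=100)
        d2 = next(h for h in hits if h.model_name == "Spaf_D2" and h.rank == 1)
        short = ProteinSequence("short", seq.residues[: d2.end - 30])
        assert detect_tail_helix_tyr(short, d2, small_library) is False


class TestMotifs:
    def test_consensus_segment_has_zero_degeneracy(self, small_library):
        model = small_library["Cdc48_D1"]
        consensus = "".join(AMINO_ACIDS[i]
                            for i in model.match_emissions.argmax(axis=1))
        seq = ProteinSequence("cons", consensus)
        path = viterbi(model, consensus)
        hit = DomainHit("cons", "Cdc48_D1", path.start, path.end,
                        path.score_bits, 1e-30, path=path)
        ann = {"walker_a": {"start": 20, "end": 28}}
        states = extract_motifs(seq, hit, model, ann)
        obs, deg = states["walker_a"]
        assert deg == pytest.approx(0.0, abs=1e-12)

    def test_scrambled_motif_approaches_full_degeneracy(self):
        # near-deterministic PFM, observed residues avoid the consensus
        pfm = np.full((4, 20), 1e-4)
        for i in range(4):
            pfm[i, i] = 1 - 19e-4
        from conftest import single_path_model
        rng = np.random.default_rng(0)
        model_cols = 4
        # craft a fake hit whose match map covers the motif directly
        seq = ProteinSequence("s", "KKKK")   # K has index 8 != 0..3
        from tandemaaa.profile_hmm import DomainPath
        path = DomainPath(10.0, 0, 4, [("M", i, i) for i in range(4)])
        hit = DomainHit("s", "m", 0, 4, 10.0, 1e-9, path=path)

        class FakeModel:
            L = 4
            match_emissions = pfm
        states = extract_motifs(seq, hit, FakeModel(), {
            "x": {"start": 0, "end": 4, "pfm": pfm}})
        _, deg = states["x"]
        assert deg > 0.999

    def test_out_of_range_motif_is_error(self, small_library):
        model = small_library["Cdc48_D1"]
        seq = ProteinSequence("s", "MKVLT" * 10)
        path = viterbi(model, seq.residues)
        hit = DomainHit("s", "Cdc48_D1", path.start, max(path.end, 1), 0.0,
                        1.0, path=path)
        with pytest.raises(ValueError, match="outside"):
            extract_motifs(seq, hit, model,
                           {"bad": {"start": 0, "end": model.L + 5}})

    def test_planted_walker_degeneracy_contrast(self, small_dataset,
                                                small_library):
        """Walker-scrambled family scores higher Walker degeneracy than an
        intact family against the canonical (intact) Walker profile."""
        from tandemaaa.synthgen import true_alignment
        from scipy.stats import mannwhitneyu
        degs = {}
        ref_ann = default_motif_annotations(small_dataset, "Cdc48", "D1")
        wa = ref_ann["walker_a"]
        ref_pfm = _motif_pfm(small_dataset, ["Cdc48", "NVL", "Spaf"], wa)
        for fam in ("Cdc48", "Pex1"):
            model = small_library[f"{fam}_D1"]
            ann_f = default_motif_annotations(small_dataset, fam, "D1")
            c0 = ann_f["walker_a"]["start"]
            c1 = ann_f["walker_a"]["end"]
            vals = []
            for p in small_dataset.proteins:
                t = small_dataset.truth_for(p.id)
                if t["family"] != fam:
                    continue
                sub = ProteinSequence(p.id, p.residues[t.d1_start:t.d1_end])
                path = viterbi(model, sub.residues)
                hit = DomainHit(p.id, model.name, path.start, path.end,
                                path.score_bits, 1e-20, path=path)
                st = extract_motifs(sub, hit, model, {
                    "walker_a": {"start": c0, "end": c1, "pfm": ref_pfm}})
                vals.append(st["walker_a"][1])
            degs[fam] = vals
        assert np.mean(degs["Pex1"]) > np.mean(degs["Cdc48"])
        p = mannwhitneyu(degs["Pex1"], degs["Cdc48"],
                         alternative="greater").pvalue
        assert p < 0.01


def _motif_pfm(ds, families, ann):
    """PFM of a motif's columns pooled over intact families' true rows."""
    from tandemaaa.synthgen import true_alignment
    from tandemaaa.seqio import AA_INDEX
    counts = np.zeros((ann["end"] - ann["start"], 20))
    for fam in families:
        aln = true_alignment(ds, fam, "D1")
        for row in aln.rows.values():
            for k, j in enumerate(range(ann["start"], ann["end"])):
                a = AA_INDEX.get(row[j])
                if a is not None:
                    counts[k, a] += 1
    return counts / counts.sum(axis=1, keepdims=True)


class TestLogo:
    def test_conserved_column_reaches_max_information(self):
        aln = MultipleAlignment({f"s{i}": "G" for i in range(10)})
        logo = compute_logo(aln)
        assert logo.info_bits[0] == pytest.approx(math.log2(20), abs=1e-9)

    def test_uniform_column_has_zero_information(self):
        aln = MultipleAlignment({f"s{i}": AMINO_ACIDS[i] for i in range(20)})
        logo = compute_logo(aln)
        assert logo.info_bits[0] == pytest.approx(0.0, abs=1e-9)

    def test_half_and_half_column(self):
        aln = MultipleAlignment(
            {f"a{i}": "A" for i in range(5)} | {f"v{i}": "V" for i in range(5)})
        logo = compute_logo(aln)
        assert logo.info_bits[0] == pytest.approx(math.log2(20) - 1.0,
                                                  abs=1e-9)

    def test_all_gap_column_flagged_with_zero_info(self):
        aln = MultipleAlignment({"a": "A-", "b": "V-"})
        logo = compute_logo(aln)
        assert logo.undefined[1] and logo.info_bits[1] == 0.0

    def test_letter_heights_sum_to_stack_height(self, small_dataset):
        from tandemaaa.synthgen import true_alignment
        aln = true_alignment(small_dataset, "NSF", "D1")
        logo = compute_logo(aln, column_range=(0, 40))
        h = logo.letter_heights()
        np.testing.assert_allclose(h.sum(axis=1),
                                   logo.info_bits * logo.columns.sum(axis=1),
                                   atol=1e-9)
        assert (logo.info_bits >= 0).all()
        assert (logo.info_bits <= math.log2(20) + 1e-12).all()

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            compute_logo(MultipleAlignment({"a": "AK"}))


def test_model_name_conventions():
    assert model_role("Cdc48_D1") == "D1"
    assert model_family("Cdc48_D1") == "Cdc48"
    assert model_role("tail_helix") == "other"
    assert model_family("Spaflike_N") == "Spaflike"
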