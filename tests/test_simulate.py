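import dataclasses

import numpy as np
import pytest
from Bio.Seq import Seq

from pbminer import simulate as sim
from pbminer.divergence import k2p
from pbminer.seqcore import needleman_wunsch, reverse_complement
from pbminer.transposase import find_orfs


class TestBuildTemplate:
    def test_designed_anatomy(self, rng):
        t = sim.build_template(rng, "T", tir_length=14, tir_motif="CCCTT")
        assert t.tir_5p.startswith("CCCTT") and len(t.tir_5p) == 14
        assert t.tir_3p == reverse_complement(t.tir_5p)
        assert 503 <= len(t.transposase) <= 1316
        assert 1230 <= len(t.full_sequence) <= 9510
        assert str(Seq(t.cds).translate())[:-1] == t.transposase
        assert all(t.transposase[d] == "D" for d in t.ddd_positions)
        assert all(t.transposase[c] == "C" for c in t.crd_cys_positions)
        d1, d2, d3 = t.ddd_positions
        assert 78 <= d2 - d1 <= 85 and 98 <= d3 - d2 <= 113

    def test_full_sequence_layout(self, rng):
        t = sim.build_template(rng, "T")
        s, e = t.cds_span
        assert t.full_sequence[s:e] == t.cds
        assert t.full_sequence.startswith(t.tir_5p)
        assert t.full_sequence.endswith(t.tir_3p)

    def test_infeasible_parameters_rejected(self, rng):
        with pytest.raises(ValueError):
            sim.build_template(rng, "T", tir_length=1000)
        with pytest.raises(ValueError):
            sim.build_template(rng, "T", transposase_len=100)


class TestEvolveCopy:
    def test_zero_divergence_is_identity(self, rng):
        t = sim.build_template(rng, "T")
        assert sim.evolve_copy(t.full_sequence, 0.0, 2.0, rng) == t.full_sequence

    def test_saturation_guard(self, rng):
        with pytest.raises(ValueError):
            sim.evolve_copy("ACGT" * 100, 0.9, 2.0, rng)

    def test_k2p_estimator_recovers_target(self, rng):
        # Monte-Carlo: expected K2P distance of evolved copies equals target
        base = "".join(rng.choice(list("ACGT"), size=5000))
        for target in (0.05, 0.10):
            ests = []
            for _ in range(40):
                mut = sim.evolve_copy(base, target, 2.0, rng)
                ests.append(k2p(base, mut).K)
            assert abs(float(np.mean(ests)) - target) < 0.01

    def test_transition_transversion_ratio_at_kappa_two(self, rng):
        # kappa = 2 means one transition class at rate 2 vs two transversion
        # classes at rate 1 each: expected count ratio 1.0
        # low divergence so multiple-hit effects do not distort the count ratio
        base = "".join(rng.choice(list("ACGT"), size=100_000))
        mut = sim.evolve_copy(base, 0.05, 2.0, rng)
        ts = tv = 0
        pur = set("AG")
        for x, y in zip(base, mut):
            if x == y:
                continue
            if (x in pur) == (y in pur):
                ts += 1
            else:
                tv += 1
        assert ts / tv == pytest.approx(1.0, abs=0.1)

    def test_preserve_orf_keeps_transposase(self, rng):
        t = sim.build_template(rng, "T")
        for target in (0.05, 0.10):
            mut = sim.evolve_copy(t.full_sequence, target, 2.0, rng, t.cds_span)
            _, longest = find_orfs(mut)
            assert longest is not None and longest.length_aa >= 500


class TestDegradeCopy:
    @pytest.fixture
    def template(self, rng):
        return sim.build_template(rng, "T", tir_length=16)

    def test_orf_disrupted_breaks_transposase(self, template, rng):
        d = sim.degrade_copy(template.full_sequence, template, "orf_disrupted", rng)
        _, longest = find_orfs(d)
        assert longest is None or longest.length_aa < 500

    def test_internal_deletion_shortens(self, template, rng):
        d = sim.degrade_copy(template.full_sequence, template, "internal_deletion", rng)
        assert len(d) < 0.9 * len(template.full_sequence)
        cds_len = template.cds_span[1] - template.cds_span[0]
        assert len(template.full_sequence) - len(d) >= 0.3 * cds_len

    def test_missing_tir_removes_one_terminus(self, template, rng):
        d = sim.degrade_copy(template.full_sequence, template, "missing_tir", rng)
        assert len(d) == len(template.full_sequence) - template.tir_length
        has5 = d.startswith(template.tir_5p)
        has3 = d.endswith(template.tir_3p)
        assert has5 != has3  # exactly one terminus survives

    def test_unknown_mode_rejected(self, template, rng):
        with pytest.raises(ValueError):
            sim.degrade_copy(template.full_sequence, template, "nonsense", rng)


class TestGenerateDataset:
    def test_determinism(self, tmp_path):
        cfg = sim.SimConfig(genome_length=120_000, n_types=2, copies_per_type=2,
                            seed=4, min_spacing_bp=8000)
        a = sim.generate_dataset(cfg)
        b = sim.generate_dataset(dataclasses.replace(cfg))
        assert a.genome.residues == b.genome.residues
        assert a.copies == b.copies
        pa = a.write(tmp_path / "a")
        pb = b.write(tmp_path / "b")
        for k in pa:
            assert pa[k].read_bytes() == pb[k].read_bytes()

    def test_tsd_duplication_on_all_planted_copies(self, small_dataset):
        g = small_dataset.genome.residues
        for c in small_dataset.copies:
            s, e = c.realized_span
            if c.integrity == "missing_tsd":
                assert g[s - 4 : s] == "TTAA"  # only the pre-existing site 4-mer
            else:
                assert g[s - 4 : s] == g[e : e + 4] == "TTAA"

    def test_planted_bp_conservation(self, small_dataset):
        total = sum(e - s for s, e in (c.realized_span for c in small_dataset.copies))
        cfg = small_dataset.config
        n_dup = sum(1 for c in small_dataset.copies if c.integrity != "missing_tsd")
        assert len(small_dataset.genome) == cfg.genome_length + total + 4 * n_dup

    def test_copies_recover_planted_sequences(self, small_dataset):
        g = small_dataset.genome.residues
        for c in small_dataset.copies:
            if c.integrity != "intact" or c.target_divergence > 0:
                continue
            s, e = c.realized_span
            seq = g[s:e]
            if c.strand == "-":
                seq = reverse_complement(seq)
            assert seq == small_dataset.templates[c.type_id].full_sequence

    def test_divergence_calibration_grid(self, rng):
        # planted copies at each grid point estimate back within 0.015
        t = sim.build_template(rng, "T", transposase_len=900)
        for target in (0.02, 0.05, 0.1, 0.2):
            errs = []
            for _ in range(25):
                mut = sim.evolve_copy(t.full_sequence, target, 2.0, rng)
                errs.append(k2p(t.full_sequence, mut).K - target)
            assert abs(float(np.mean(errs))) < 0.015

    def test_insufficient_space_rejected(self):
        cfg = sim.SimConfig(genome_length=30_000, n_types=4, copies_per_type=8,
                            seed=1, min_spacing_bp=10_000)
        with pytest.raises(ValueError):
            sim.generate_dataset(cfg)

    def test_seed_mandatory_and_fraction_ranges(self):
        with pytest.raises(ValueError):
            sim.SimConfig(seed=None).validate()
        with pytest.raises(ValueError):
            sim.SimConfig(gc_fraction=1.4).validate()
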