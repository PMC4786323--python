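"""Generator invariants: barcode design, fragment structure, planted
variants, read emission and determinism."""

import itertools

import numpy as np
import pytest

from radpop import (
    SimulationConfig,
    generate_reference_fragments,
    generate_toy_transcriptome,
    hamming,
    make_barcode_set,
    plant_variants,
    simulate_dataset,
    simulate_rad_reads,
)
from radpop.simulate import ECORI_SITE, TAG_LENGTH, VARIABLE_REGION


class TestBarcodes:
    def test_pairwise_distance_brute_force(self):
        barcodes = make_barcode_set(18, (4, 8), min_distance=2, seed=1)
        assert len(barcodes) == 18
        assert all(4 <= len(b) <= 8 for b in barcodes)
        for a, b in itertools.combinations(barcodes, 2):
            if len(a) == len(b):
                assert sum(x != y for x, y in zip(a, b)) >= 2
            # variable-length sets must stay prefix-free for exact matching
            assert not a.startswith(b) and not b.startswith(a)

    def test_single_barcode(self):
        assert len(make_barcode_set(1, (4, 4), seed=0)) == 1

    def test_two_barcodes_length4(self):
        a, b = make_barcode_set(2, (4, 4), min_distance=2, seed=3)
        assert hamming(a, b) >= 2

    def test_deterministic(self):
        assert make_barcode_set(10, (4, 8), seed=7) == make_barcode_set(
            10, (4, 8), seed=7
        )

    def test_infeasible_request_fails(self):
        # >64 length-4 barcodes at distance >=2 cannot exist
        with pytest.raises(ValueError):
            make_barcode_set(80, (4, 4), min_distance=2, seed=0)


class TestFragments:
    def test_fragments_start_with_site(self):
        cfg = SimulationConfig(n_fragments=100, repeat_fraction=0.0, seed=2)
        frags = generate_reference_fragments(cfg)
        assert len(frags) == 100
        assert all(f.sequence.startswith(ECORI_SITE) for f in frags)

    def test_zero_fragments(self):
        cfg = SimulationConfig(n_fragments=0, seed=2)
        assert generate_reference_fragments(cfg) == []

    def test_repeat_fraction_creates_near_duplicates(self):
        cfg = SimulationConfig(
            n_fragments=100, repeat_fraction=0.1, repeat_copy_number=2, seed=4
        )
        frags = generate_reference_fragments(cfg)
        # brute-force duplicate detection: high-identity pairs
        with_partner = set()
        for a, b in itertools.combinations(frags, 2):
            if hamming(a.sequence, b.sequence) <= 4:
                with_partner.update((a.id, b.id))
        assert len(with_partner) >= 20  # 10 sources + 10 copies


class TestPlantVariants:
    def test_variant_positions_in_variable_window(self):
        cfg = SimulationConfig(n_fragments=200, seed=5)
        frags = generate_reference_fragments(cfg)
        truth = plant_variants(frags, cfg)
        lo, hi = VARIABLE_REGION
        assert ((truth.loci["pos"] >= lo) & (truth.loci["pos"] < hi)).all()
        assert (truth.loci["ref"] != truth.loci["alt"]).all()

    def test_zero_het_rate_gives_no_heterozygotes(self):
        cfg = SimulationConfig(
            n_fragments=100,
            het_rate_by_group={g: 0.0 for g in "Css Csa Ctl Ccc Ctg Ctb".split()},
            admixture_parents=("Csa", "Ctl"),
            seed=6,
        )
        frags = generate_reference_fragments(cfg)
        truth = plant_variants(frags, cfg)
        # admixed haplotypes come from parental groups, which are now fixed,
        # so any remaining hets would be admixed-only
        non_admixed = [
            a
            for a in truth.accessions
            if cfg.class_of_group[cfg.group_of[a]] != "admixed"
        ]
        for acc in non_admixed:
            for g in truth.genotypes[acc]:
                assert g == "" or g[0] == g[1]

    def test_selected_loci_fixed_in_cultivated(self):
        cfg = SimulationConfig(
            n_fragments=300, fixed_cultivated_fraction=0.2, seed=7
        )
        frags = generate_reference_fragments(cfg)
        truth = plant_variants(frags, cfg)
        cult = cfg.accessions_in_class("cultivated")
        selected = truth.loci.index[truth.loci["selected"]]
        assert len(selected) > 0
        for locus in selected:
            genos = {
                truth.genotypes.at[locus, a]
                for a in cult
                if truth.genotypes.at[locus, a] != ""
            }
            assert len(genos) == 1
            (g,) = genos
            assert g[0] == g[1]

    def test_transition_fraction_recovered(self):
        cfg = SimulationConfig(
            n_fragments=2000, repeat_fraction=0.0, transition_fraction=0.6, seed=8
        )
        frags = generate_reference_fragments(cfg)
        truth = plant_variants(frags, cfg)
        is_ti = [
            {r, a} in ({"A", "G"}, {"C", "T"})
            for r, a in zip(truth.loci["ref"], truth.loci["alt"])
        ]
        n = len(is_ti)
        sd = np.sqrt(0.6 * 0.4 / n)
        assert abs(np.mean(is_ti) - 0.6) < 3 * sd


class TestReads:
    def test_depth_law_and_conservation(self):
        cfg = SimulationConfig(
            n_fragments=1,
            repeat_fraction=0.0,
            missing_rate=0.0,
            error_rate=0.0,
            low_quality_read_fraction=0.0,
            mean_depth=40,
            seed=9,
        )
        ds = simulate_dataset(cfg)
        assert len(ds.reads) == sum(ds.reads.counts.values())
        counts = list(ds.reads.counts.values())
        assert len(counts) == 18
        # mean of 18 Poisson(40) draws within 3 SD
        assert abs(np.mean(counts) - 40) < 3 * np.sqrt(40 / 18)

    def test_error_free_reads_show_only_true_alleles(self):
        cfg = SimulationConfig(
            n_fragments=5,
            repeat_fraction=0.0,
            missing_rate=0.0,
            error_rate=0.0,
            low_quality_read_fraction=0.0,
            seed=10,
        )
        ds = simulate_dataset(cfg)
        bc_by_prefix = sorted(ds.barcodes.values(), key=len, reverse=True)
        frag_by_tag = {
            row["tag"]: (locus, row)
            for locus, row in ds.truth.loci.iterrows()
        }
        for _, seq, _ in ds.reads:
            bc = next(b for b in bc_by_prefix if seq.startswith(b))
            tag = seq[len(bc) : len(bc) + TAG_LENGTH]
            for ref_tag, (locus, row) in frag_by_tag.items():
                if hamming(tag, ref_tag) <= 2:
                    base = tag[row["pos"]]
                    assert base in (row["ref"], row["alt"])
                    break

    def test_missing_accession_yields_no_reads(self):
        cfg = SimulationConfig(n_fragments=5, missing_rate=1.0, seed=11)
        ds = simulate_dataset(cfg)
        assert len(ds.reads) == 0

    def test_byte_identical_for_fixed_seed(self):
        cfg = SimulationConfig(n_fragments=10, seed=12)
        d1, d2 = simulate_dataset(cfg), simulate_dataset(cfg)
        assert d1.reads.reads == d2.reads.reads
        assert d1.truth.genotypes.equals(d2.truth.genotypes)
        assert d1.truth.loci.drop(columns="haplotypes").equals(
            d2.truth.loci.drop(columns="haplotypes")
        )


class TestToyTranscriptome:
    def test_embedding_and_effect_truth(self):
        cfg = SimulationConfig(n_fragments=80, seed=13)
        frags = generate_reference_fragments(cfg)
        truth = plant_variants(frags, cfg)
        tx, cds, effects = generate_toy_transcriptome(
            truth, n_embedded=40, coding_fraction=0.7, seed=14
        )
        assert len(tx) == 40
        embedded = effects[effects["effect"] != "unmapped"]
        assert len(embedded) == 40
        assert set(embedded["effect"]) <= {
            "synonymous",
            "non_synonymous",
            "non_coding",
        }
        # coding effects exist in both classes and CDS spans whole codons
        assert (embedded["effect"] == "non_coding").sum() > 0
        assert ((cds["cds_end"] - cds["cds_start"]) % 3 == 0).all()
        # embedded region (or its reverse complement) really is a substring
        from radpop import revcomp

        for locus, row in embedded.iterrows():
            lo, hi = VARIABLE_REGION
            region = truth.loci.at[locus, "tag"][lo:hi]
            if row["strand"] == "-":
                region = revcomp(region)
            assert region in tx[row["transcript_id"]]
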