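"""Gene-drop simulator: determinism, pedigree F, IBD truth calibration."""

from __future__ import annotations

import numpy as np
import pytest

from herdgen.dataset import MISSING
from herdgen.sim import (
    PedigreeRecord,
    gene_drop,
    make_conservation_pedigree,
    pedigree_inbreeding,
    simulate_family_dataset,
    simulate_founder_haplotypes,
    simulate_wright_fisher,
)


def trio(n_gen_loop: str = "fullsib") -> list[PedigreeRecord]:
    """Founders F1 x F2 -> sibs S1, S2 -> inbred offspring O."""
    ped = [
        PedigreeRecord("F1", None, None, "male", "fam"),
        PedigreeRecord("F2", None, None, "female", "fam"),
        PedigreeRecord("S1", "F1", "F2", "male", "fam", 1),
        PedigreeRecord("S2", "F1", "F2", "female", "fam", 1),
        PedigreeRecord("O", "S1", "S2", "female", "fam", 2),
    ]
    return ped


class TestPedigreeInbreeding:
    def test_classic_designs(self):
        """Path-counting F: selfing 0.5, full-sib 0.25, half-sib 0.125."""
        selfing = [
            PedigreeRecord("A", None, None, "male", "f"),
            PedigreeRecord("O", "A", "A", "male", "f", 1),
        ]
        assert pedigree_inbreeding(selfing)["O"] == pytest.approx(0.5)

        assert pedigree_inbreeding(trio())["O"] == pytest.approx(0.25)

        halfsib = [
            PedigreeRecord("F1", None, None, "male", "f"),
            PedigreeRecord("F2", None, None, "female", "f"),
            PedigreeRecord("F3", None, None, "female", "f"),
            PedigreeRecord("S1", "F1", "F2", "male", "f", 1),
            PedigreeRecord("S2", "F1", "F3", "female", "f", 1),
            PedigreeRecord("O", "S1", "S2", "female", "f", 2),
        ]
        assert pedigree_inbreeding(halfsib)["O"] == pytest.approx(0.125)

    def test_founders_have_zero_f(self):
        f = pedigree_inbreeding(trio())
        assert f["F1"] == f["F2"] == 0.0

    def test_unknown_parent_rejected(self):
        bad = [PedigreeRecord("O", "ghost", "ghost2", "male", "f")]
        with pytest.raises(ValueError):
            pedigree_inbreeding(bad)


class TestFounderHaplotypes:
    def test_same_seed_identical_pool(self):
        a = simulate_founder_haplotypes(5, 50, 2, seed=3)
        b = simulate_founder_haplotypes(5, 50, 2, seed=3)
        for c in range(2):
            assert np.array_equal(a.haplotypes[c], b.haplotypes[c])
            assert np.array_equal(a.positions[c], b.positions[c])

    def test_degenerate_maf_distribution(self, rng):
        """MAF fixed at 0.5: empirical founder MAF concentrates near 0.5."""
        pool = simulate_founder_haplotypes(
            200, 300, 1, maf_distribution=lambda r, size: np.full(size, 0.5), seed=4
        )
        emp = pool.haplotypes[0].mean(axis=0)
        emp_maf = np.minimum(emp, 1 - emp)
        # binomial SE of a frequency over 400 haplotypes is 0.025
        assert emp_maf.mean() > 0.5 - 3 * 0.025

    def test_invalid_maf_bounds_rejected(self):
        with pytest.raises(ValueError):
            simulate_founder_haplotypes(
                5, 10, 1, maf_distribution=lambda r, size: np.full(size, 0.7)
            )


class TestGeneDrop:
    def test_no_recombination_limit(self):
        """cm_per_mb = 0: inherited haplotypes are intact parental copies."""
        ped = trio()
        pool = simulate_founder_haplotypes(2, 100, 3, seed=5)
        ds, truth = gene_drop(ped, pool, cm_per_mb=0.0, seed=6)
        # every IBD segment of O spans a whole chromosome or is absent
        for seg in truth.true_ibd_segments["O"]:
            assert seg.start_bp == 1
            assert seg.end_bp == pool.chrom_length_bp + 1

    def test_founders_have_no_ibd(self):
        ped = trio()
        pool = simulate_founder_haplotypes(2, 50, 2, seed=7)
        _, truth = gene_drop(ped, pool, seed=8)
        assert truth.true_ibd_segments["F1"] == []
        assert truth.true_ibd_segments["F2"] == []

    def test_same_seed_identical_output(self):
        ped = trio()
        pool = simulate_founder_haplotypes(2, 50, 2, seed=9)
        ds1, _ = gene_drop(ped, pool, seed=10, missing_rate=0.05)
        ds2, _ = gene_drop(ped, pool, seed=10, missing_rate=0.05)
        assert np.array_equal(ds1.calls, ds2.calls)

    def test_fullsib_ibd_fraction_near_quarter(self):
        """Mean genome-wide IBD of full-sib offspring ≈ pedigree F = 0.25."""
        pool = simulate_founder_haplotypes(2, 10, 4, seed=11, chrom_length_bp=10**8)
        genome = 4 * 10**8
        fracs = []
        for seed in range(300):
            _, truth = gene_drop(trio(), pool, seed=seed, genotyped_ids=["O"])
            total = sum(s.length_bp for s in truth.true_ibd_segments["O"])
            fracs.append(total / genome)
        fracs = np.asarray(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - 0.25) < 3 * se + 1e-9

    def test_dataset_passes_invariants_and_groups(self, family_sim):
        ds, truth = family_sim
        ds.validate()
        assert all(s.group_label in ("boar", "sow") for s in ds.samples)
        assert (ds.calls == MISSING).mean() == pytest.approx(0.02, abs=0.005)
        # IBD truth segments never overlap within an individual-chromosome
        for segs in truth.true_ibd_segments.values():
            by_chrom: dict[int, list] = {}
            for s in segs:
                by_chrom.setdefault(s.chromosome, []).append(s)
            for lst in by_chrom.values():
                lst.sort(key=lambda s: s.start_bp)
                for a, b in zip(lst, lst[1:]):
                    assert a.end_bp <= b.start_bp


class TestConservationPedigree:
    def test_study_sized_population(self):
        ped = make_conservation_pedigree(
            n_families=8, boars_per_family=4, sows_per_family=22, n_generations=2
        )
        last = [r for r in ped if r.generation == 2]
        boars = [r for r in last if r.sex == "male"]
        sows = [r for r in last if r.sex == "female"]
        assert len(boars) == 32 and len(sows) == 176
        assert len({r.family_label for r in ped}) == 8

    def test_no_loops_no_inbreeding(self):
        ped = make_conservation_pedigree(
            n_families=2,
            boars_per_family=2,
            sows_per_family=4,
            n_generations=1,
            inbred_loop_fraction=0.0,
        )
        assert all(r.expected_pedigree_F == 0.0 for r in ped)

    def test_loops_create_inbreeding(self):
        ped = make_conservation_pedigree(
            n_families=2,
            boars_per_family=3,
            sows_per_family=6,
            n_generations=3,
            inbred_loop_fraction=0.8,
            seed=2,
        )
        last = [r for r in ped if r.generation == 3]
        assert any(r.expected_pedigree_F >= 0.125 for r in last)

    def test_same_seed_identical(self):
        a = make_conservation_pedigree(seed=5)
        b = make_conservation_pedigree(seed=5)
        assert [(r.individual_id, r.sire_id, r.dam_id) for r in a] == [
            (r.individual_id, r.sire_id, r.dam_id) for r in b
        ]

    def test_impossible_configuration_rejected(self):
        with pytest.raises(ValueError):
            make_conservation_pedigree(n_families=0)


class TestWrightFisher:
    def test_same_seed_identical(self):
        a = simulate_wright_fisher(10, 5, 10, 50, seed=1)
        b = simulate_wright_fisher(10, 5, 10, 50, seed=1)
        assert np.array_equal(a.calls, b.calls)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            simulate_wright_fisher(1, 5, 1, 50)
        with pytest.raises(ValueError):
            simulate_wright_fisher(10, 5, 11, 50)

    def test_small_ne_has_more_ld(self):
        """LD at long range is higher under Ne=20 than Ne=500 (paired seeds)."""
        from herdgen.ldne import binned_r2

        edges = np.array([500_000, 5_000_000])
        wins = 0
        for seed in range(3):
            r2 = {}
            for ne in (20, 500):
                ds = simulate_wright_fisher(
                    ne, 30, 20, 120, chrom_length_bp=20_000_000, seed=seed,
                    n_chroms=2,
                )
                bins, _ = binned_r2(ds, bin_edges_bp=edges)
                r2[ne] = bins[0].mean_r2
            wins += r2[20] > r2[500]
        assert wins == 3


class TestFamilyDatasetWrapper:
    def test_reproducible_and_config_recorded(self):
        ds1, t1 = simulate_family_dataset(
            n_families=2, boars_per_family=2, sows_per_family=3,
            n_generations=2, n_chroms=2, n_markers_per_chrom=80, seed=6,
        )
        ds2, _ = simulate_family_dataset(
            n_families=2, boars_per_family=2, sows_per_family=3,
            n_generations=2, n_chroms=2, n_markers_per_chrom=80, seed=6,
        )
        assert np.array_equal(ds1.calls, ds2.calls)
        for key in ("n_families", "master_seed", "inbred_loop_fraction"):
            assert key in t1.sim_config
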