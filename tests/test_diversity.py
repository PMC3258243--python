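import itertools
import math

import numpy as np
import pandas as pd
import pytest

import barcodelim as bl


class TestSorensen:
    @pytest.mark.parametrize(
        "a, b, c, expected",
        [
            (11, 6, 1, 0.12),   # two sparsely overlapping localities
            (5, 5, 5, 1.0),
            (7, 9, 0, 0.0),
        ],
    )
    def test_values(self, a, b, c, expected):
        assert round(bl.sorensen(a, b, c), 2) == expected

    def test_shared_exceeding_either_site_is_error(self):
        with pytest.raises(bl.ValidationError):
            bl.sorensen(3, 5, 4)

    def test_empty_site_is_error(self):
        with pytest.raises(bl.ValidationError):
            bl.sorensen(0, 5, 0)


class TestSorensenMatrix:
    def test_montane_valley_localities(self, balim_incidence):
        """Four-locality community with 11/6/13/19 species reproduces the
        expected pairwise similarities."""
        sm = bl.sorensen_matrix(balim_incidence)
        q = sm.qs
        expected = {
            ("Bokondini", "Habbema"): 0.12,
            ("Bokondini", "Jiwika"): 0.25,
            ("Bokondini", "Poga"): 0.13,
            ("Habbema", "Jiwika"): 0.32,
            ("Habbema", "Poga"): 0.32,
            ("Jiwika", "Poga"): 0.38,
        }
        for (s1, s2), val in expected.items():
            assert round(q.loc[s1, s2], 2) == val
        assert list(sm.richness[["Bokondini", "Habbema", "Jiwika", "Poga"]]) == [
            11, 6, 13, 19,
        ]

    def test_disjoint_sites_zero(self):
        cm = bl.CommunityMatrix.from_occurrences(
            [("s1", "A"), ("s2", "A"), ("s3", "B")]
        )
        sm = bl.sorensen_matrix(cm)
        assert sm.qs.loc["A", "B"] == 0.0

    def test_matches_set_operations_oracle(self, rng):
        species = [f"sp{i}" for i in range(40)]
        sites = ["s1", "s2", "s3", "s4"]
        occ = [
            (sp, site)
            for sp in species
            for site in sites
            if rng.random() < 0.4
        ]
        present = {sp for sp, _ in occ}
        occ += [(sp, "s1") for sp in species if sp not in present]
        cm = bl.CommunityMatrix.from_occurrences(occ)
        sm = bl.sorensen_matrix(cm)
        sets = {
            site: {sp for sp, s in occ if s == site} for site in sites
        }
        for s1, s2 in itertools.combinations(sites, 2):
            a, b = len(sets[s1]), len(sets[s2])
            c = len(sets[s1] & sets[s2])
            assert sm.shared.loc[s1, s2] == c
            assert sm.qs.loc[s1, s2] == pytest.approx(2 * c / (a + b))

    def test_qs_invariants_on_random_incidence(self, rng):
        for _ in range(20):
            inc = pd.DataFrame(
                rng.integers(0, 2, size=(15, 4)),
                index=[f"sp{i}" for i in range(15)],
                columns=list("ABCD"),
            )
            # make sure every species occurs somewhere
            inc.iloc[:, 0] = (
                inc.iloc[:, 0] | (inc.sum(axis=1) == 0)
            ).astype(int)
            sm = bl.sorensen_matrix(bl.CommunityMatrix(inc))
            q = sm.qs.to_numpy()
            defined = ~np.isnan(q)
            assert ((q[defined] >= 0) & (q[defined] <= 1)).all()
            np.testing.assert_allclose(
                np.nan_to_num(q), np.nan_to_num(q.T)
            )

    def test_identical_sites_give_one(self):
        cm = bl.CommunityMatrix.from_occurrences(
            [(f"sp{i}", s) for i in range(5) for s in ("A", "B")]
        )
        assert bl.sorensen_matrix(cm).qs.loc["A", "B"] == 1.0


class TestOccupancy:
    def test_all_single_site(self):
        cm = bl.CommunityMatrix.from_occurrences(
            [(f"sp{i}", f"s{i % 3}") for i in range(9)]
        )
        out = bl.occupancy_summary(cm)
        assert out.loc[0, "pct_species"] == 100.0

    def test_one_cosmopolitan_species(self):
        occ = [(f"sp{i}", "A") for i in range(4)] + [
            ("spX", s) for s in ("A", "B", "C")
        ]
        out = bl.occupancy_summary(bl.CommunityMatrix.from_occurrences(occ))
        assert out.loc[2, "n_species"] == 1

    def test_histogram_sums_to_species_count(self, balim_incidence):
        out = bl.occupancy_summary(balim_incidence)
        assert out.n_species.sum() == len(balim_incidence.species)
        assert out.pct_species.sum() == pytest.approx(100.0)


class TestCICompare:
    def test_degenerate_equal_values_inside(self):
        res = bl.ci_compare([90.0] * 7, 90.0)
        assert not res.outside
        assert res.lower == res.upper == 90.0

    def test_degenerate_equal_values_pooled_differs(self):
        assert bl.ci_compare([90.0] * 7, 91.0).outside

    def test_symmetric_values_pooled_at_mean_inside(self):
        vals = [97, 98, 99, 101, 102, 103, 100]
        res = bl.ci_compare(vals, float(np.mean(vals)))
        assert not res.outside
        assert res.lower <= res.mean <= res.upper

    def test_true_mean_coverage_near_nominal(self):
        """95% CI on the mean of 7 values misses the true mean ~5% of the
        time (seeded simulation)."""
        rng = np.random.default_rng(99)
        misses = sum(
            bl.ci_compare(rng.normal(100.0, 5.0, size=7), 100.0).outside
            for _ in range(2000)
        )
        assert 0.03 <= misses / 2000 <= 0.08

    def test_needs_two_values(self):
        with pytest.raises(bl.ValidationError):
            bl.ci_compare([1.0], 1.0)


class TestRegionalLocalSweep:
    def test_twelve_rows_for_default_thresholds(self):
        cfg = bl.GeneratorConfig(n_species=40, seed=3)
        aln, table, _ = bl.simulate_sequences(cfg)
        comp = bl.regional_local_sweep(aln, table)
        assert len(comp.table) == 12
        assert set(comp.per_area.area) <= set(table.areas)
        lo = comp.table.agreement_ci_lower
        hi = comp.table.agreement_ci_upper
        mean = comp.table.agreement_area_mean
        assert ((lo <= mean + 1e-9) & (mean <= hi + 1e-9)).all()

    def test_no_geographic_structure_rarely_flags(self):
        """Without geographic substructure or label errors, pooled and
        per-area clustering agree at thresholds inside the barcoding gap
        (flags only appear once the threshold reaches the interspecific
        band, ~11% and beyond)."""
        clean = 0
        for seed in range(5):
            cfg = bl.GeneratorConfig(
                n_species=80, geo_fraction=0.0, cryptic_fraction=0.0,
                oversplit_fraction=0.0, unassigned_fraction=0.0, seed=seed,
            )
            aln, table, _ = bl.simulate_sequences(cfg)
            comp = bl.regional_local_sweep(
                aln, table, thresholds=[t / 100 for t in range(1, 11)]
            )
            flags = comp.table[["agreement_outside", "accuracy_outside"]]
            clean += not flags.any(axis=None)
        assert clean >= 4

    def test_divergent_subpopulations_depress_one_areas_accuracy(self):
        """An area whose species carry two divergent haplogroups (>threshold
        apart) is oversplit locally, giving it the lowest accuracy."""
        rng = np.random.default_rng(8)
        bases = np.array(list("ACGT"))
        records, rows = [], []
        for si in range(12):
            anc = rng.integers(0, 4, 400)
            divergent = anc.copy()
            hot = rng.choice(400, 24, replace=False)  # ~6% away haplogroup
            divergent[hot] = (divergent[hot] + rng.integers(1, 4, 24)) % 4
            for area in ("deep", "flat1", "flat2"):
                seqs = [anc, divergent] if area == "deep" else [anc, anc]
                for rep, s in enumerate(seqs):
                    sid = f"sp{si:02d}-{area}-{rep}"
                    records.append((sid, "".join(bases[s])))
                    rows.append((sid, f"sp{si:02d}", area, f"{area}-L1"))
        aln = bl.Alignment.from_pairs(records)
        table = bl.SpecimenTable.from_records(rows)
        comp = bl.regional_local_sweep(aln, table, thresholds=[0.03])
        per = comp.per_area.set_index("area")
        assert per.loc["deep", "accuracy_pct"] == per.accuracy_pct.min()
        assert per.loc["deep", "agreement_pct"] == per.agreement_pct.max()

    def test_tiny_area_excluded(self):
        cfg = bl.GeneratorConfig(n_species=20, seed=4)
        aln, table, _ = bl.simulate_sequences(cfg)
        df = table.df.copy()
        extra = pd.DataFrame(
            [{"specimen_id": "lone", "morphospecies": "spX",
              "area": "area99", "locality": "area99-L1"}]
        )
        table2 = bl.SpecimenTable(pd.concat([df, extra], ignore_index=True))
        aln2 = bl.Alignment.from_pairs(
            list(zip(aln.ids, aln.seqs)) + [("lone", aln.seqs[0])]
        )
        comp = bl.regional_local_sweep(aln2, table2, thresholds=[0.03])
        assert "area99" not in comp.areas
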