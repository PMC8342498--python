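import numpy as np
import pandas as pd
import pytest

from brewptm.quant_normalize import (
    build_dataset,
    collapse_replicates,
    family_normalize,
    family_occupancy,
    fdr_filter,
    occupancy_summary,
    protein_abundance,
)


def make_data(entries):
    """entries: (form_id, sample, replicate, intensity, fdr)"""
    return pd.DataFrame(
        entries,
        columns=["form_id", "sample_id", "replicate", "intensity", "fdr"],
    )


def make_forms(rows):
    """rows: dicts with form_id plus any of the forms-table columns."""
    defaults = dict(accession="P1", species="barley", peptide="PEP",
                    start=1, end=3, cleavage="full_tryptic", mod_kind="",
                    hex=0, hexnac=0, site=-1, family="P1:1-3")
    frame = pd.DataFrame([{**defaults, **r} for r in rows])
    return frame.set_index("form_id")


class TestFdrFilter:
    def test_retained_and_removed(self):
        d = make_data([("f", "s", "r1", 10.0, 0.005),
                       ("g", "s", "r1", 20.0, 0.02)])
        out, n = fdr_filter(d, 0.01)
        assert n == 1
        assert out.loc[0, "intensity"] == 10.0
        assert np.isnan(out.loc[1, "intensity"])

    def test_derived_enumeration(self):
        # 10 entries with fdr 0.001 + 0.011*i; brute-force count of survivors
        fdrs = [0.001 + 0.011 * i for i in range(10)]
        d = make_data([(f"f{i}", "s", "r1", 1.0, q)
                       for i, q in enumerate(fdrs)])
        expected_kept = sum(q <= 0.01 for q in fdrs)
        out, n = fdr_filter(d, 0.01)
        assert out["intensity"].notna().sum() == expected_kept
        assert n == 10 - expected_kept

    def test_bad_cutoff(self):
        with pytest.raises(ValueError):
            fdr_filter(make_data([]), 0.0)


class TestCollapseReplicates:
    def test_mean(self):
        d = make_data([("f", "s", f"r{i}", v, 0.001)
                       for i, v in enumerate((10.0, 20.0, 30.0))])
        assert collapse_replicates(d, "mean").loc["f", "s"] == 20.0

    def test_median(self):
        d = make_data([("f", "s", f"r{i}", v, 0.001)
                       for i, v in enumerate((1.0, 100.0, 100.0))])
        assert collapse_replicates(d, "median").loc["f", "s"] == 100.0

    def test_mean_ignores_missing(self):
        d = make_data([("f", "s", "r1", 10.0, 0.001),
                       ("f", "s", "r2", np.nan, 0.001),
                       ("f", "s", "r3", 30.0, 0.001)])
        assert collapse_replicates(d, "mean").loc["f", "s"] == 20.0

    def test_all_missing_is_missing(self):
        d = make_data([("f", "s", "r1", np.nan, 0.001),
                       ("f", "t", "r1", 5.0, 0.001)])
        wide = collapse_replicates(d, "mean")
        assert np.isnan(wide.loc["f", "s"])

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            collapse_replicates(make_data([]), "mode")


class TestFamilyNormalize:
    def _famtab(self, intensities):
        forms = make_forms([{"form_id": k} for k in intensities])
        wide = pd.DataFrame({"s1": intensities})
        return family_normalize(wide, forms)

    def test_hand_arithmetic(self):
        # {unmodified: 80, Hex1: 15, Hex2: 5} -> {0.80, 0.15, 0.05}
        ft = self._famtab({"u": 80.0, "h1": 15.0, "h2": 5.0})
        props = ft.set_index("form_id")["proportion"]
        assert props["u"] == pytest.approx(0.80)
        assert props["h1"] == pytest.approx(0.15)
        assert props["h2"] == pytest.approx(0.05)

    def test_singleton_family(self):
        ft = self._famtab({"u": 42.0})
        assert ft["proportion"].iloc[0] == 1.0

    def test_zero_total_is_undefined(self):
        ft = self._famtab({"u": 0.0, "h1": 0.0})
        assert ft["proportion"].isna().all()
        assert (ft["family_total"] == 0).all()

    def test_missing_counts_zero_in_denominator(self):
        ft = self._famtab({"u": 80.0, "h1": np.nan, "h2": 20.0})
        props = ft.set_index("form_id")["proportion"]
        assert props["u"] == pytest.approx(0.8)
        assert props["h1"] == 0.0

    def test_proportions_sum_to_one_randomized(self):
        # spec invariant at 1e-9 over randomized synthetic matrices
        rng = np.random.default_rng(0)
        for _ in range(200):
            n_fams = rng.integers(1, 6)
            rows, intensities = [], []
            for f in range(n_fams):
                for m in range(rng.integers(1, 5)):
                    rows.append({"form_id": f"F{f}M{m}",
                                 "family": f"P1:{f}-{f}"})
                    intensities.append(rng.uniform(0.1, 1e6))
            forms = make_forms(rows)
            wide = pd.DataFrame({"s1": intensities},
                                index=[r["form_id"] for r in rows])
            ft = family_normalize(wide, forms)
            sums = ft.groupby("family")["proportion"].sum()
            assert np.allclose(sums, 1.0, atol=1e-9)

    def test_per_replicate_order_agrees_when_noise_free(self):
        from brewptm.quant_normalize import family_normalize_per_replicate

        forms = make_forms([{"form_id": "u"}, {"form_id": "h1"}])
        entries = []
        for rep in ("r1", "r2", "r3"):
            entries += [("u", "s1", rep, 80.0, 0.001),
                        ("h1", "s1", rep, 20.0, 0.001)]
        data = make_data(entries)
        a = family_normalize(collapse_replicates(data), forms)
        b = family_normalize_per_replicate(data, forms)
        pa = a.set_index("form_id")["proportion"]
        pb = b.set_index("form_id")["proportion"]
        assert pa["u"] == pytest.approx(pb["u"], abs=1e-12)
        assert pb["h1"] == pytest.approx(0.2)
        sums = b.groupby("family")["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        rows = [{"form_id": f"m{i}"} for i in range(4)]
        forms = make_forms(rows)
        vals = rng.uniform(1, 100, 4)
        a = family_normalize(pd.DataFrame({"s1": vals},
                             index=[r["form_id"] for r in rows]), forms)
        b = family_normalize(pd.DataFrame({"s1": vals * 3.7},
                             index=[r["form_id"] for r in rows]), forms)
        assert np.allclose(a["proportion"], b["proportion"])


class TestOccupancy:
    def _setup(self):
        forms = make_forms([
            {"form_id": "a_u", "family": "P1:1-9"},
            {"form_id": "a_h1", "family": "P1:1-9",
             "mod_kind": "o_glyc_hex", "hex": 1},
            {"form_id": "a_h2", "family": "P1:1-9",
             "mod_kind": "o_glyc_hex", "hex": 2},
            {"form_id": "b_u", "family": "P1:20-30"},
            {"form_id": "b_h1", "family": "P1:20-30",
             "mod_kind": "o_glyc_hex", "hex": 1},
        ])
        wide = pd.DataFrame(
            {"s1": [80.0, 15.0, 5.0, 60.0, 40.0]},
            index=["a_u", "a_h1", "a_h2", "b_u", "b_h1"],
        )
        return forms, family_normalize(wide, forms)

    def test_arithmetic_oracle(self):
        forms, ft = self._setup()
        occ = occupancy_summary(ft, forms, "glycosylation")
        # family occupancies 0.20 and 0.40 -> total 0.60, average 0.30
        assert occ["total"].iloc[0] == pytest.approx(0.60)
        assert occ["average"].iloc[0] == pytest.approx(0.30)
        assert occ["n_families"].iloc[0] == 2

    def test_no_modified_forms_anywhere(self):
        forms = make_forms([{"form_id": "u"}])
        ft = family_normalize(pd.DataFrame({"s1": [10.0]}, index=["u"]),
                              forms)
        occ = occupancy_summary(ft, forms, "glycation")
        assert len(occ) == 0  # no eligible families -> empty with warning

    def test_proteolysis_uses_cleavage(self):
        forms = make_forms([
            {"form_id": "full", "family": "P1:1-9"},
            {"form_id": "clip", "family": "P1:1-9",
             "cleavage": "semi_tryptic"},
        ])
        wide = pd.DataFrame({"s1": [70.0, 30.0]}, index=["full", "clip"])
        ft = family_normalize(wide, forms)
        occ = occupancy_summary(ft, forms, "proteolysis")
        assert occ["total"].iloc[0] == pytest.approx(0.30)

    def test_brute_force_equality_random_families(self):
        # spec invariant: occupancy equals brute-force recomputation from
        # the raw per-sample matrix on 1,000 random families
        rng = np.random.default_rng(3)
        rows, intensities, truth = [], [], {}
        for f in range(1000):
            fam = f"P1:{f}-{f}"
            n_mod = int(rng.integers(1, 4))
            vals = rng.uniform(0.0, 100.0, size=n_mod + 1)
            rows.append({"form_id": f"F{f}_u", "family": fam})
            intensities.append(vals[0])
            for m in range(n_mod):
                rows.append({"form_id": f"F{f}_m{m}", "family": fam,
                             "mod_kind": "glycation_hex", "hex": 1})
                intensities.append(vals[m + 1])
            total = vals.sum()
            truth[fam] = vals[1:].sum() / total if total > 0 else None
        forms = make_forms(rows)
        wide = pd.DataFrame({"s1": intensities},
                            index=[r["form_id"] for r in rows])
        ft = family_normalize(wide, forms)
        occ = family_occupancy(ft, forms, "glycation")
        est = occ.set_index("family")["occupancy"]
        for fam, expect in truth.items():
            if expect is None:
                assert fam not in est.index
            else:
                assert est[fam] == pytest.approx(expect, abs=1e-12)

    def test_unknown_kind(self):
        forms, ft = self._setup()
        with pytest.raises(ValueError):
            occupancy_summary(ft, forms, "phospho")


class TestProteinAbundance:
    def _forms(self):
        return make_forms([
            {"form_id": "a1", "accession": "A", "family": "A:1-3"},
            {"form_id": "a2", "accession": "A", "family": "A:5-9"},
            {"form_id": "b1", "accession": "B", "family": "B:1-3"},
            {"form_id": "t1", "accession": "TRY", "species": "trypsin",
             "family": "TRY:1-3"},
            {"form_id": "c1", "accession": "CON", "species": "contaminant",
             "family": "CON:1-3"},
        ])

    def _wide(self):
        return pd.DataFrame(
            {"s1": [50.0, 10.0, 40.0, 10.0, 7.0]},
            index=["a1", "a2", "b1", "t1", "c1"],
        )

    def test_norm_total_oracle(self):
        pa = protein_abundance(self._wide(), self._forms(), mode="total")
        norm = pa.set_index("accession")["norm"]
        assert norm["A"] == pytest.approx(0.6)
        assert norm["B"] == pytest.approx(0.4)
        assert "TRY" not in norm.index and "CON" not in norm.index

    def test_norm_total_sums_to_one(self):
        pa = protein_abundance(self._wide(), self._forms(), mode="total")
        assert pa.groupby("sample_id")["norm"].sum().iloc[0] == \
            pytest.approx(1.0, abs=1e-9)

    def test_trypsin_mode_oracle(self):
        pa = protein_abundance(self._wide(), self._forms(), mode="trypsin")
        norm = pa.set_index("accession")["norm"]
        assert norm["A"] == pytest.approx(6.0)   # 60 / 10
        assert norm["B"] == pytest.approx(4.0)

    def test_single_protein_sample(self):
        forms = make_forms([{"form_id": "a1", "accession": "A"}])
        wide = pd.DataFrame({"s1": [5.0]}, index=["a1"])
        pa = protein_abundance(wide, forms, mode="total")
        assert pa["norm"].iloc[0] == 1.0

    def test_trypsin_mode_without_trypsin_errors(self):
        forms = make_forms([{"form_id": "a1", "accession": "A"}])
        wide = pd.DataFrame({"s1": [5.0]}, index=["a1"])
        with pytest.raises(ValueError, match="trypsin"):
            protein_abundance(wide, forms, mode="trypsin")

    def test_scaling_invariance(self):
        pa1 = protein_abundance(self._wide(), self._forms(), mode="total")
        pa2 = protein_abundance(self._wide() * 11.0, self._forms(),
                                mode="total")
        assert np.allclose(pa1["norm"], pa2["norm"])

    def test_log10_floor_rule(self):
        forms = make_forms([
            {"form_id": "a1", "accession": "A"},
            {"form_id": "b1", "accession": "B"},
        ])
        wide = pd.DataFrame({"s1": [5.0, 0.0]}, index=["a1", "b1"])
        pa = protein_abundance(wide, forms, mode="total")
        log10 = pa.set_index("accession")["log10_norm"]
        assert log10["A"] == pytest.approx(0.0)  # norm 1.0
        assert np.isnan(log10["B"])              # zero stays missing


class TestBuildDataset:
    def test_roundtrip_and_common_mod_collapse(self, toy_db):
        quant = pd.DataFrame([
            # same backbone+rare-mod state, differing only in oxidation:
            # must merge into one form with summed intensity
            dict(sample_id="s1", replicate="r1", accession="NLTP1",
                 peptide="MKPCLTYVQGGPGPSGECCNGVR", prev_aa="K", next_aa="S",
                 mods="Hex(2)@K2", intensity=10.0, fdr=0.001),
            dict(sample_id="s1", replicate="r1", accession="NLTP1",
                 peptide="MKPCLTYVQGGPGPSGECCNGVR", prev_aa="K", next_aa="S",
                 mods="Hex(2)@K2;Oxidized@M1", intensity=5.0, fdr=0.002),
            dict(sample_id="s1", replicate="r1", accession="GLT3",
                 peptide="VVDQQLVGQLPWSTGLQMQ", prev_aa="R", next_aa="C",
                 mods="unmodified", intensity=3.0, fdr=0.003),
            # a bad row: must be rejected, not raise
            dict(sample_id="s1", replicate="r1", accession="GLT3",
                 peptide="WWWWW", prev_aa="-", next_aa="-",
                 mods="unmodified", intensity=1.0, fdr=0.001),
        ])
        ds = build_dataset(quant, toy_db)
        assert ds.n_rejected() == 1
        assert len(ds.forms) == 2
        merged = ds.data[ds.data["form_id"].str.startswith("NLTP1")]
        assert len(merged) == 1
        assert merged["intensity"].iloc[0] == pytest.approx(15.0)
        assert merged["fdr"].iloc[0] == pytest.approx(0.001)
        clip = ds.forms[ds.forms["cleavage"] == "semi_tryptic"]
        assert list(clip["family"]) == ["GLT3:56-80"]

    def test_missing_columns(self, toy_db):
        with pytest.raises(ValueError, match="missing columns"):
            build_dataset(pd.DataFrame({"sample_id": []}), toy_db)
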