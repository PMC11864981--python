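"""Generator truths: determinism, planted signals, construction checks."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import spotgin as sg
from spotgin.synthetic import (REFERENCE_ZONES, TUMOR_ZONES, hex_grid,
                               stripe_widths, zone_map)


class TestLattice:
    def test_hex_spacing(self):
        coords = hex_grid(6, 6)
        xy = coords[["px_x", "px_y"]].to_numpy()
        from scipy.spatial.distance import pdist
        assert pdist(xy).min() == pytest.approx(100.0)

    def test_zone_map_is_contiguous_and_complete(self):
        coords = hex_grid(20, 20)
        zones = zone_map(coords)
        assert set(zones) == {"main tumor", "infiltrative tumor", "necrosis",
                              "white matter", "cortex"}
        # zones are vertical bands: column order sorts the labels
        frame = pd.DataFrame({"col": coords["array_col"], "zone": zones})
        order = frame.groupby("zone")["col"].agg(["min", "max"])
        intervals = order.sort_values("min")
        assert (intervals["min"].to_numpy()[1:]
                > intervals["max"].to_numpy()[:-1]).all()

    def test_stripe_widths_balanced(self):
        for rows in (24, 30):
            for w in stripe_widths(rows, 4):
                pattern = (np.arange(rows) // w) % 2
                assert pattern.mean() == 0.5

    def test_too_many_classes_error(self):
        with pytest.raises(ValueError, match="stripe"):
            stripe_widths(8, 4)


class TestCohort:
    def test_expected_spot_count(self, small_cohort):
        assert all(ds.n_spots == 144 for ds in small_cohort.datasets)

    def test_regeneration_is_byte_identical(self, tmp_path):
        import filecmp
        for run in ("a", "b"):
            cohort = sg.generate_cohort(n_samples=2, grid=(10, 10),
                                        n_genes=250, n_classes=2, seed=33,
                                        subclass_mode="marginal")
            sg.save_cohort(cohort, tmp_path / run)
        cmp = filecmp.dircmp(tmp_path / "a", tmp_path / "b")
        assert not cmp.diff_files

    def test_generated_files_pass_readers(self, tmp_path, small_cohort):
        sg.save_cohort(small_cohort, tmp_path)
        d = tmp_path / "SYN00"
        ds = sg.read_counts(d / "matrix.mtx", d / "features.tsv",
                            d / "barcodes.tsv")
        ds = sg.attach_positions(ds, d / "tissue_positions.csv")
        ds.histology = sg.read_histology(d / "histology.tsv")
        ds.validate()
        genes = sg.read_gene_bed(tmp_path / "genes.bed")
        assert len(genes) == 250

    def test_texture_classes_marginally_indistinguishable(self):
        """Texture-pair construction: per-spot signature means match across
        classes (t-test non-significant for >=90% of signature genes)."""
        cohort = sg.generate_cohort(n_samples=4, grid=(24, 24), n_genes=300,
                                    n_classes=4, seed=44,
                                    subclass_mode="texture", events=None)
        sig_genes = (cohort.truth.program_genes["texture0"]
                     + cohort.truth.program_genes["texture1"])
        a, b = cohort.datasets[0], cohort.datasets[1]
        idx = pd.Index(a.gene_ids).get_indexer(sig_genes)
        ca = a.counts.toarray()[idx]
        cb = b.counts.toarray()[idx]
        insignificant = 0
        for g in range(len(sig_genes)):
            _, p = scipy.stats.ttest_ind(ca[g], cb[g], equal_var=False)
            insignificant += p > 0.05
        assert insignificant >= 0.9 * len(sig_genes)

    def test_mgmt_program_shifts_tumor_expression(self, rng):
        cohort = sg.generate_cohort(n_samples=2, grid=(14, 14), n_genes=250,
                                    n_classes=2, seed=55,
                                    subclass_mode="marginal", events=None)
        meth = cohort.datasets[0]    # even index: methylated
        unmeth = cohort.datasets[1]
        assert meth.labels.mgmt_status == "methylated"
        genes = cohort.truth.program_genes["mgmt"]
        idx = pd.Index(meth.gene_ids).get_indexer(genes)
        tumor = meth.histology.isin(TUMOR_ZONES).to_numpy()
        m = meth.counts.toarray()[idx][:, tumor].mean()
        u = unmeth.counts.toarray()[idx][:, tumor].mean()
        assert m > 2.0 * u


class TestPlantCnv:
    def test_gain_scales_mean_expression(self):
        with_event = sg.generate_cohort(
            n_samples=1, grid=(16, 16), n_genes=400, n_classes=2, seed=66,
            subclass_mode="marginal",
            events={"SYN00": [("chr7", "p", "gain")]})
        without = sg.generate_cohort(
            n_samples=1, grid=(16, 16), n_genes=400, n_classes=2, seed=66,
            subclass_mode="marginal", events=None)
        genes = with_event.genes
        mids = (genes["start"] + genes["end"]) // 2
        on_arm = ((genes["chrom"] == "chr7")
                  & (mids <= with_event.arms["chr7"])).to_numpy()
        ds_e, ds_0 = with_event.datasets[0], without.datasets[0]
        tumor = ds_e.histology.isin(TUMOR_ZONES).to_numpy()
        m_e = ds_e.counts.toarray()[on_arm][:, tumor].mean()
        m_0 = ds_0.counts.toarray()[on_arm][:, tumor].mean()
        assert m_e / m_0 == pytest.approx(1.5, rel=0.10)

    def test_no_events_reference_all_neutral(self):
        cohort = sg.generate_cohort(n_samples=1, grid=(10, 10), n_genes=250,
                                    n_classes=2, seed=1, events=None,
                                    subclass_mode="marginal")
        ref = cohort.truth.reference_calls["SYN00"]
        assert set(ref.values()) == {0}
        assert len(ref) == 16  # every autosome arm present

    def test_event_ledger_matches_reference_rows(self):
        cohort = sg.generate_cohort(n_samples=3, grid=(10, 10), n_genes=250,
                                    n_classes=2, seed=2,
                                    subclass_mode="marginal")
        for sid, events in cohort.truth.events.items():
            ref = cohort.truth.reference_calls[sid]
            altered = {f"{c}{a}" for c, a, _ in events}
            for arm, call in ref.items():
                assert (call != 0) == (arm in altered)


class TestMarkerImage:
    def test_same_seed_identical_image(self, small_cohort):
        ds = small_cohort.datasets[0]
        nm = sg.normalize_dataset(ds)
        sg.select_hvg_joint([nm], 20)
        gene = str(nm.hvg_ids[0])
        sg.render_marker_image(ds, nm, gene, seed=3)
        img1 = ds.image.copy()
        sg.render_marker_image(ds, nm, gene, seed=3)
        assert np.array_equal(img1, ds.image)

    def test_intensity_in_blue_channel(self, small_cohort):
        ds = small_cohort.datasets[0]
        nm = sg.normalize_dataset(ds)
        sg.select_hvg_joint([nm], 20)
        sg.render_marker_image(ds, nm, str(nm.hvg_ids[0]), seed=3)
        assert ds.image.dtype == np.uint8
        assert ds.image[..., 0].std() == 0  # red constant
        assert ds.image[..., 2].std() > 0   # signal in blue


class TestDeconvolution:
    @pytest.fixture(scope="class")
    def dec(self, small_dataset):
        return sg.generate_deconvolution(small_dataset, n_types=4, seed=8)

    def test_healthy_zones_fewer_cells(self, small_dataset, dec):
        counts = dec["true_counts"].sum(axis=1)
        zones = small_dataset.histology
        healthy = counts[zones.isin(REFERENCE_ZONES)].mean()
        tumor = counts[zones == "main tumor"].mean()
        assert healthy < tumor

    def test_nuclei_match_counts(self, dec):
        per_spot = dec["nuclei"].groupby("barcode").size()
        totals = dec["true_counts"].sum(axis=1)
        for barcode, n in per_spot.items():
            assert n == totals[barcode]

    def test_noiseless_scores_recover_truth(self, small_dataset):
        dec = sg.generate_deconvolution(small_dataset, n_types=4,
                                        noise_sd=0.0, seed=9)
        for barcode in dec["scores"].index[:50]:
            row = dec["scores"].loc[barcode].to_numpy()
            n = int(dec["true_counts"].loc[barcode].sum())
            if n == 0 or row.sum() == 0:
                continue
            out = sg.allocate_cells(row, n)
            assert np.array_equal(out,
                                  dec["true_counts"].loc[barcode].to_numpy())

    def test_high_concentration_near_uniform(self, small_dataset):
        dec = sg.generate_deconvolution(small_dataset, n_types=4,
                                        concentration=5000.0, seed=10)
        props = dec["scores"].div(dec["scores"].sum(axis=1), axis=0).dropna()
        assert np.allclose(props.mean(axis=0), 0.25, atol=0.02)
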