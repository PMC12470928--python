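"""Synthetic cohort generator: truths, reads, traces, determinism."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import epitarget as et
from epitarget.cohort import SANGER_MISSING_DEFAULTS, non_cpg_c_offsets


@pytest.fixture(scope="module")
def cfg():
    return et.default_config(seed=7, coverage=200)


class TestGenerateCohort:
    def test_default_cohort_composition(self, cfg):
        cohort = et.generate_cohort(cfg)
        labels = pd.Series([s.label for s in cohort]).value_counts()
        assert len(cohort) == 99
        assert labels["control"] == 30
        assert labels["rts1"] == 60
        assert labels["vus"] == 5
        assert labels["overlap"] == 4

    def test_zero_noise_gives_exact_centres(self):
        cfg = et.default_config(seed=0, biological_sd=0.0)
        site = min(cfg.control_baseline)
        cohort = et.generate_cohort(cfg)
        for s in cohort:
            expected = cfg.control_baseline[site]
            if s.label in {"rts1", "vus"}:
                expected += cfg.case_delta[site]
            assert s.true_methylation[site] == pytest.approx(expected)

    def test_overlap_samples_use_control_centre(self):
        cfg = et.default_config(seed=0, biological_sd=0.0, n_overlap=4)
        cohort = et.generate_cohort(cfg)
        controls = [s for s in cohort if s.label == "control"]
        overlaps = [s for s in cohort if s.label == "overlap"]
        assert overlaps[0].true_methylation == controls[0].true_methylation

    def test_deterministic_under_seed(self, cfg):
        a = et.generate_cohort(cfg)
        b = et.generate_cohort(cfg)
        assert a == b

    def test_law_of_large_numbers_recovers_baseline_and_delta(self):
        cfg = et.default_config(seed=3, n_control=500, n_case=500, n_vus=0, n_overlap=0)
        cohort = et.generate_cohort(cfg)
        site = 10556199
        ctrl = np.array(
            [s.true_methylation[site] for s in cohort if s.label == "control"]
        )
        case = np.array([s.true_methylation[site] for s in cohort if s.label == "rts1"])
        tol = 3 * cfg.biological_sd / np.sqrt(500)
        assert abs(ctrl.mean() - cfg.control_baseline[site]) <= tol
        assert abs((case.mean() - ctrl.mean()) - cfg.case_delta[site]) <= 2 * tol

    def test_beta_noise_model_stays_in_range_and_matches_centre(self):
        cfg = et.default_config(
            seed=11, n_control=300, n_case=0, n_vus=0, n_overlap=0,
            noise_model="beta",
        )
        cohort = et.generate_cohort(cfg)
        site = min(cfg.control_baseline)
        values = np.array([s.true_methylation[site] for s in cohort])
        assert ((values >= 0) & (values <= 100)).all()
        assert abs(values.mean() - cfg.control_baseline[site]) <= 3 * cfg.biological_sd / np.sqrt(300)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            et.default_config(n_control=-1)


class TestSyntheticReferences:
    def test_cpgs_only_at_designed_offsets(self, panel, refs):
        for a in panel:
            seq = refs[a.locus_id]
            assert len(seq) == a.insert_length
            found = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]
            assert found == sorted(a.cpg_offsets())

    def test_non_cpg_cytosines_exist_for_qc(self, panel, refs):
        for a in panel:
            assert non_cpg_c_offsets(refs[a.locus_id], a.cpg_offsets()).size > 10


class TestSimulateReads:
    def test_fully_methylated_reads_show_c_everywhere(
        self, panel, refs, flat_truth_factory
    ):
        cfg = et.default_config(
            seed=0, coverage=50, conversion_efficiency=1.0, seq_error_rate=0.0
        )
        reads = et.simulate_reads(flat_truth_factory(100.0), panel, refs, cfg)
        for a in panel:
            block = reads[a.locus_id][:, list(a.cpg_offsets())]
            assert (block == ord("C")).all()

    def test_fully_unmethylated_reads_show_t_everywhere(
        self, panel, refs, flat_truth_factory
    ):
        cfg = et.default_config(
            seed=0, coverage=50, conversion_efficiency=1.0, seq_error_rate=0.0
        )
        reads = et.simulate_reads(flat_truth_factory(0.0), panel, refs, cfg)
        for a in panel:
            block = reads[a.locus_id][:, list(a.cpg_offsets())]
            assert (block == ord("T")).all()

    def test_binomial_recovery_at_deep_coverage(
        self, panel, refs, flat_truth_factory
    ):
        cfg = et.default_config(
            seed=0, coverage=8000, conversion_efficiency=1.0, seq_error_rate=0.0
        )
        reads = et.simulate_reads(flat_truth_factory(80.0), panel, refs, cfg)
        meth, _ = et.quantify_sample(reads, panel, refs)
        for a in panel:
            for p in a.encompassed_cpgs:
                assert meth[f"{a.insert_chrom}:{p}"] == pytest.approx(80.0, abs=2.0)

    def test_deterministic_and_missing_reference_rejected(
        self, panel, refs, flat_truth_factory, cfg
    ):
        truth = flat_truth_factory(50.0)
        a = et.simulate_reads(truth, panel, refs, cfg, rng=np.random.default_rng(5))
        b = et.simulate_reads(truth, panel, refs, cfg, rng=np.random.default_rng(5))
        for locus in a:
            assert (a[locus] == b[locus]).all()
        with pytest.raises(KeyError):
            et.simulate_reads(truth, panel, {}, cfg)

    def test_fastq_round_trip(self, panel, refs, flat_truth_factory, tmp_path):
        from Bio import SeqIO

        cfg = et.default_config(seed=0, coverage=5)
        reads = et.simulate_reads(flat_truth_factory(50.0), panel, refs, cfg)
        records = et.cohort.reads_to_fastq(reads["1.1"], "s1", "1.1")
        path = tmp_path / "s1.fastq"
        et.cohort.write_fastq(records, path)
        back = list(SeqIO.parse(str(path), "fastq"))
        assert len(back) == 5
        assert str(back[0].seq) == reads["1.1"][0].tobytes().decode()


class TestSimulateTraces:
    def test_noise_free_amplitudes_follow_truth(self, panel, flat_truth_factory):
        cfg = et.default_config(seed=0, trace_noise_cv=0.0)
        cfg = replace(cfg, sanger_missing_rate={})
        for level, t_factor, c_factor in [(0.0, 1.0, 0.0), (100.0, 0.0, 1.0)]:
            traces = et.simulate_traces(flat_truth_factory(level), panel, cfg)
            for trace in traces:
                cpg = trace.peaks[trace.peaks["kind"] == "cpg"]
                for _, row in cpg.iterrows():
                    ctx = cfg.context_amplitude[row["genomic_position"]]
                    expect = ctx * (t_factor if row["channel"] == "T" else c_factor)
                    assert row["amplitude"] == pytest.approx(expect)

    def test_structurally_missing_site_absent_from_every_trace(
        self, panel, flat_truth_factory
    ):
        assert SANGER_MISSING_DEFAULTS[206628592] == 1.0
        cfg = et.default_config(seed=0)
        for i in range(5):
            truth = replace(flat_truth_factory(50.0), sample_id=f"s{i}")
            traces = et.simulate_traces(
                truth, panel, cfg, rng=np.random.default_rng(i)
            )
            for trace in traces:
                assert 206628592 not in trace.cpg_positions()

    def test_trace_determinism_and_tsv_round_trip(
        self, panel, flat_truth_factory, tmp_path
    ):
        from epitarget.sanger import read_traces_tsv, write_traces_tsv

        cfg = et.default_config(seed=0)
        truth = flat_truth_factory(40.0)
        a = et.simulate_traces(truth, panel, cfg, rng=np.random.default_rng(9))
        b = et.simulate_traces(truth, panel, cfg, rng=np.random.default_rng(9))
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.peaks, y.peaks)
        path = tmp_path / "traces.tsv"
        write_traces_tsv(a, path)
        back = read_traces_tsv(path)
        assert [t.locus_id for t in back] == [t.locus_id for t in a]
        for x, y in zip(a, back):
            np.testing.assert_allclose(
                x.peaks["amplitude"], y.peaks["amplitude"], rtol=1e-12
            )

    def test_model_traces_are_unmethylated_replicates(self, panel):
        cfg = et.default_config(seed=0, trace_noise_cv=0.0, n_model_traces=3)
        models = et.simulate_model_traces(panel, cfg)
        assert len(models) == 3 * len(panel)
        for trace in models:
            cpg = trace.peaks[trace.peaks["kind"] == "cpg"]
            c_rows = cpg[cpg["channel"] == "C"]
            assert (c_rows["amplitude"] == 0).all()
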