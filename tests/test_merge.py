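"""Streaming merge: registry, fill, row splicing, end-to-end runs."""

import gzip

import pytest

from vcfmerge import (
    CohortSpec,
    DesyncError,
    FormatError,
    MergeConfig,
    MergeError,
    VariantKey,
    generate_cohort,
    merge_batches,
    merge_variant_row,
    missing_fill,
    resolve_duplicates,
    split_into_batches,
    stream_vcf_records,
)
from vcfmerge.plan import combine_records
from vcfmerge.formats import BatchInfoRecord


class TestResolveDuplicates:
    def test_disjoint_batches_unchanged(self):
        reg = resolve_duplicates([["A", "B"], ["C", "D"]])
        assert reg.output_ids == ["A", "B", "C", "D"]
        assert reg.duplicates == {}

    def test_shared_id_gets_numbered_suffix(self):
        reg = resolve_duplicates([["A", "B"], ["B", "C"]])
        assert reg.output_ids == ["A", "B", "B:2", "C"]
        assert list(reg.duplicates) == ["B"]
        assert reg.duplicates["B"] == [(0, "B"), (1, "B:2")]

    def test_id_in_three_batches(self):
        reg = resolve_duplicates([["X"], ["X"], ["X"]])
        assert reg.output_ids == ["X", "X:2", "X:3"]

    def test_renamed_id_colliding_with_real_id_gets_further_suffix(self):
        # batch 1 contains both a duplicate of X and a literal sample 'X:2'
        reg = resolve_duplicates([["X"], ["X:2", "X"]])
        assert len(set(reg.output_ids)) == len(reg.output_ids)
        assert reg.output_ids[0] == "X"
        assert "X:2" in reg.output_ids  # the literal one keeps its name

    @pytest.mark.parametrize("n_batches,n_shared", [(2, 0), (2, 2), (3, 5), (4, 3)])
    def test_uniqueness_exhaustive_over_collision_fixtures(self, n_batches, n_shared):
        shared = [f"D{i}" for i in range(n_shared)]
        batches = [shared + [f"B{b}_{i}" for i in range(4)] for b in range(n_batches)]
        reg = resolve_duplicates(batches)
        assert len(set(reg.output_ids)) == len(reg.output_ids)
        assert len(reg.output_ids) == sum(len(b) for b in batches)
        assert sorted(reg.duplicates) == sorted(shared)
        # within-batch order preserved, batches concatenated in order
        flat = [sid for b in batches for sid in b]
        assert [o.split(":")[0] for o in reg.output_ids] == flat


class TestMissingFill:
    @pytest.mark.parametrize(
        "fmt,n,expected",
        [
            ("GT", 3, [".|.", ".|.", ".|."]),
            ("GT:DS", 1, [".|.:."]),
            ("GT:DS:GP", 2, [".|.:.:.", ".|.:.:."]),
        ],
    )
    def test_fill_patterns(self, fmt, n, expected):
        assert missing_fill(fmt, n) == expected

    def test_format_without_gt_rejected(self):
        with pytest.raises(FormatError, match="GT"):
            missing_fill("DS:GP", 2)


def _row(pos, gts, fmt="GT:DS", info="AF=0.2;MAF=0.2;R2=0.9;IMPUTED"):
    return ["chr1", str(pos), ".", "A", "G", ".", "PASS", info, fmt] + list(gts)


def _combined(key, afs_ns):
    per_batch = [
        None if af is None else BatchInfoRecord(key=key, af=af, maf=min(af, 1 - af),
                                                rsq=0.9, genotyped=False, n_samples=n)
        for af, n in afs_ns
    ]
    return combine_records(key, per_batch)


class TestMergeVariantRow:
    KEY = VariantKey("chr1", 100, "A", "G")

    def test_single_batch_identity_up_to_info(self):
        reg = resolve_duplicates([["S1", "S2"]])
        row = _row(100, ["0|1:1.0", "1|1:2.0"])
        combined = _combined(self.KEY, [(0.2, 2)])
        merged = merge_variant_row(self.KEY, [row], combined, reg)
        assert merged[9:] == row[9:]
        assert merged[:7] == row[:7]
        assert "TYPED_STATUS=none" in merged[7]

    def test_absent_batch_gets_missing_fill(self):
        reg = resolve_duplicates([["S1", "S2"], ["T1", "T2", "T3"]])
        row = _row(100, ["0|1:1.0", "1|1:2.0"])
        combined = _combined(self.KEY, [(0.2, 2), (None, 3)])
        merged = merge_variant_row(self.KEY, [row, None], combined, reg)
        assert len(merged) == 9 + 5
        assert merged[11:] == [".|.:.", ".|.:.", ".|.:."]

    def test_two_present_batches_concatenate_like_manual_splice(self):
        reg = resolve_duplicates([["S1", "S2"], ["T1"]])
        r0 = _row(100, ["0|1:1.0", "1|1:2.0"])
        r1 = _row(100, ["0|0:0.1"])
        combined = _combined(self.KEY, [(0.2, 2), (0.1, 1)])
        merged = merge_variant_row(self.KEY, [r0, r1], combined, reg)
        assert merged[9:] == r0[9:] + r1[9:]

    def test_info_rewritten_with_combined_values(self):
        reg = resolve_duplicates([["S1"], ["T1"]])
        r0 = _row(100, ["0|1:1.0"], info="AF=0.1;MAF=0.1;R2=0.5;OTHER=keepme;IMPUTED")
        r1 = _row(100, ["0|0:0.0"])
        combined = _combined(self.KEY, [(0.1, 1), (0.3, 1)])
        merged = merge_variant_row(self.KEY, [r0, r1], combined, reg)
        info = dict(
            t.split("=", 1) if "=" in t else (t, True) for t in merged[7].split(";")
        )
        assert float(info["AF"]) == pytest.approx(0.2)
        assert float(info["MAF"]) == pytest.approx(0.2)
        assert float(info["R2"]) == pytest.approx(combined.rsq_combined, rel=1e-5)
        assert info["OTHER"] == "keepme"  # unrecognized tokens preserved
        assert info["TYPED_STATUS"] == "none"

    def test_format_conflict_is_fatal(self):
        reg = resolve_duplicates([["S1"], ["T1"]])
        r0 = _row(100, ["0|1:1.0"], fmt="GT:DS")
        r1 = _row(100, ["0|0"], fmt="GT")
        combined = _combined(self.KEY, [(0.1, 1), (0.3, 1)])
        with pytest.raises(MergeError, match="FORMAT"):
            merge_variant_row(self.KEY, [r0, r1], combined, reg)


def read_merged_genotypes(path):
    """(sample_ids, {key: [GT strings]}) from a merged VCF."""
    from vcfmerge import read_vcf_header

    samples = read_vcf_header(path).sample_ids
    rows = {}
    for key, fields in stream_vcf_records(path):
        rows[key] = [cell.split(":")[0] for cell in fields[9:]]
    return samples, rows


class TestMergeBatches:
    @pytest.mark.parametrize("k", [2, 3])
    def test_round_trip_reconstructs_genotype_matrix(self, tmp_path, k, small_cohort):
        """Splitting a cohort column-wise and merging back must reproduce
        every genotype exactly, with samples in registry order."""
        cohort = small_cohort
        man = split_into_batches(cohort, tmp_path, k=k)
        cfg = MergeConfig(vcf_paths=man.vcf_paths, out_prefix=str(tmp_path / "out"))
        summary = merge_batches(cfg)
        assert summary.n_retained == 50
        assert summary.n_samples == 6
        samples, rows = read_merged_genotypes(tmp_path / "out.vcf.gz")
        assert samples == cohort.sample_ids
        for j, key in enumerate(cohort.keys):
            expected = [f"{cohort.genotypes[j, i, 0]}|{cohort.genotypes[j, i, 1]}"
                        for i in range(6)]
            assert rows[key] == expected

    def test_private_variant_filled_or_excluded(self, tmp_path, small_cohort):
        man = split_into_batches(
            small_cohort, tmp_path, k=3, private_variant_counts=[0, 1, 0]
        )
        private_key = next(k for k, pres in man.presence.items() if sum(pres) == 1)
        out = tmp_path / "keep"
        summary = merge_batches(
            MergeConfig(vcf_paths=man.vcf_paths, missing_allowance=2,
                        out_prefix=str(out))
        )
        assert summary.n_retained == 50
        _, rows = read_merged_genotypes(f"{out}.vcf.gz")
        gts = rows[private_key]
        sizes = [len(ids) for ids in man.batch_sample_ids]
        assert gts[: sizes[0]] == [".|."] * sizes[0]
        assert gts[sizes[0] + sizes[1]:] == [".|."] * sizes[2]
        assert all(g != ".|." for g in gts[sizes[0]: sizes[0] + sizes[1]])

        strict = merge_batches(
            MergeConfig(vcf_paths=man.vcf_paths, missing_allowance=0,
                        out_prefix=str(tmp_path / "strict"))
        )
        assert strict.n_retained == 49
        assert strict.n_excluded_missing == 1
        _, strict_rows = read_merged_genotypes(tmp_path / "strict.vcf.gz")
        assert private_key not in strict_rows
        excluded_text = (tmp_path / "strict_excluded.info.txt").read_text()
        assert str(private_key) in excluded_text
        assert "too-many-missing" in excluded_text

    def test_duplicates_file_lists_shared_ids(self, tmp_path, small_cohort):
        man = split_into_batches(small_cohort, tmp_path, k=2, overlap=2)
        summary = merge_batches(
            MergeConfig(vcf_paths=man.vcf_paths, out_prefix=str(tmp_path / "out"))
        )
        assert summary.n_samples == 8  # 6 + 2 duplicated columns
        assert summary.n_duplicates == 2
        dup_lines = (tmp_path / "duplicates.txt").read_text().splitlines()[1:]
        assert {l.split("\t")[0] for l in dup_lines} == set(man.duplicated_ids)
        samples, _ = read_merged_genotypes(tmp_path / "out.vcf.gz")
        assert len(set(samples)) == len(samples)

    def test_desync_between_info_and_vcf_detected(self, tmp_path, small_cohort):
        man = split_into_batches(small_cohort, tmp_path, k=2)
        # claim an extra variant in batch 0's info table that the VCF lacks
        info0 = man.info_paths[0]
        lines = gzip.open(info0, "rt").read().splitlines()
        phantom = "chr1:999999:A:G\tA\tG\t0.1\t0.1\t-\t0.5\tImputed"
        with gzip.open(info0, "wt") as fh:
            fh.write("\n".join(lines + [phantom]) + "\n")
        with pytest.raises((DesyncError, FormatError)):
            merge_batches(
                MergeConfig(vcf_paths=man.vcf_paths, missing_allowance=1,
                            out_prefix=str(tmp_path / "out"))
            )
        assert not (tmp_path / "out.vcf.gz").exists()  # partial output removed

    def test_log_and_summary_agree(self, tmp_path, small_cohort):
        man = split_into_batches(small_cohort, tmp_path, k=2)
        out = tmp_path / "out"
        summary = merge_batches(
            MergeConfig(vcf_paths=man.vcf_paths, out_prefix=str(out))
        )
        log = (tmp_path / "out.log").read_text()
        assert f"retained variants: {summary.n_retained}" in log
        assert f"output samples: {summary.n_samples}" in log

    def test_output_positions_nondecreasing(self, tmp_path, small_cohort):
        man = split_into_batches(small_cohort, tmp_path, k=3)
        merge_batches(MergeConfig(vcf_paths=man.vcf_paths, out_prefix=str(tmp_path / "out")))
        positions = [k.pos for k, _ in stream_vcf_records(tmp_path / "out.vcf.gz")]
        assert positions == sorted(positions)
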