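"""Catalogue/signature I/O and VCF extraction against hand-tallied fixtures."""

import numpy as np
import pandas as pd
import pytest

import sigrefit as sr
from sigrefit.channels import CHANNEL_LABELS
from sigrefit.fixtures import EXPECTED


def _as_dict(cat):
    s = cat.to_series()
    return {k: int(v) for k, v in s[s > 0].items()}


class TestVcfExtraction:
    def test_default_policy_hand_tally(self, fixture_dir):
        with pytest.warns(UserWarning, match="ambiguous"):
            cat = sr.vcf_to_catalogue(fixture_dir["vcf"], fixture_dir["fasta"])
        exp = EXPECTED["vcf_default"]
        assert _as_dict(cat) == exp["channels"]
        assert cat.total == exp["total"]
        assert cat.provenance["skipped"] == exp["skipped"]
        # conservation: catalogue total equals accepted-record count
        assert cat.total == cat.provenance["accepted"]

    def test_pass_only_policy(self, fixture_dir):
        policy = sr.VcfFilterPolicy(require_pass=True)
        with pytest.warns(UserWarning, match="ambiguous"):
            cat = sr.vcf_to_catalogue(fixture_dir["vcf"], fixture_dir["fasta"], policy)
        exp = EXPECTED["vcf_pass_only"]
        assert _as_dict(cat) == exp["channels"]
        assert cat.provenance["skipped"] == exp["skipped"]

    def test_ref_mismatch_is_hard_error(self, fixture_dir, tmp_path):
        vcf = tmp_path / "bad.vcf"
        text = fixture_dir["vcf"].read_text().replace(
            "chr1\t3\t.\tC\tT\t.\tPASS\t.", "chr1\t3\t.\tG\tT\t.\tPASS\t."
        )
        vcf.write_text(text)
        with pytest.raises(ValueError, match="REF mismatch"):
            sr.vcf_to_catalogue(vcf, fixture_dir["fasta"])

    def test_empty_vcf_gives_zero_catalogue(self, fixture_dir, tmp_path):
        vcf = tmp_path / "empty.vcf"
        header = "\n".join(
            line
            for line in fixture_dir["vcf"].read_text().splitlines()
            if line.startswith("#")
        )
        vcf.write_text(header + "\n")
        cat = sr.vcf_to_catalogue(vcf, fixture_dir["fasta"])
        assert cat.total == 0
        assert np.all(cat.values == 0)

    def test_non_snv_cannot_be_admitted(self):
        with pytest.raises(ValueError):
            sr.VcfFilterPolicy(skip_non_snv=False)

    def test_strand_collapse_involution(self, fixture_dir, tmp_path):
        """Reverse-complementing the reference (and the VCF records with it)
        must produce the identical catalogue."""
        from pyfaidx import Fasta

        fa = Fasta(str(fixture_dir["fasta"]))
        lengths = {name: len(fa[name]) for name in fa.keys()}
        with open(tmp_path / "rc.fa", "w") as fh:
            for name in fa.keys():
                fh.write(f">{name}\n{sr.reverse_complement(str(fa[name][:]))}\n")
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        out_lines = []
        for line in fixture_dir["vcf"].read_text().splitlines():
            if line.startswith("#"):
                out_lines.append(line)
                continue
            chrom, pos, vid, ref, alt, qual, filt, info = line.split("\t")
            new_pos = lengths[chrom] - int(pos) + 1
            new_ref = "".join(comp.get(b, b) for b in reversed(ref))
            new_alt = ",".join(
                "".join(comp.get(b, b) for b in reversed(a)) for a in alt.split(",")
            )
            out_lines.append(
                "\t".join([chrom, str(new_pos), vid, new_ref, new_alt, qual, filt, info])
            )
        # records must stay coordinate-sorted for the insertion to stay an
        # insertion we just drop it: its anchor base flips under revcomp
        body = [l for l in out_lines if not l.startswith("#")]
        body = [l for l in body if "\tC\tCA\t" not in l and "\tG\tTG\t" not in l]
        body.sort(key=lambda l: (l.split("\t")[0], int(l.split("\t")[1])))
        header = [l for l in out_lines if l.startswith("#")]
        (tmp_path / "rc.vcf").write_text("\n".join(header + body) + "\n")

        with pytest.warns(UserWarning, match="ambiguous"):
            original = sr.vcf_to_catalogue(fixture_dir["vcf"], fixture_dir["fasta"])
        with pytest.warns(UserWarning, match="ambiguous"):
            flipped = sr.vcf_to_catalogue(tmp_path / "rc.vcf", tmp_path / "rc.fa")
        # the dropped insertion never entered a channel, so counts agree
        assert np.array_equal(original.values, flipped.values)


class TestCatalogueTables:
    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        cats = [
            sr.MutationalCatalogue(f"s{i}", rng.integers(0, 50, 96).astype(float))
            for i in range(4)
        ]
        path = tmp_path / "cat.tsv"
        sr.write_catalogue_table(cats, path, header_lines=["round trip"])
        back = sr.read_catalogue_table(path)
        assert [c.sample_id for c in back] == [c.sample_id for c in cats]
        for a, b in zip(cats, back):
            assert np.array_equal(a.values, b.values)
        # writing again is bit-identical
        path2 = tmp_path / "cat2.tsv"
        sr.write_catalogue_table(back, path2, header_lines=["round trip"])
        assert path.read_text() == path2.read_text()

    def test_rows_reordered_to_canonical_order(self, tmp_path):
        rng = np.random.default_rng(4)
        values = rng.integers(0, 20, 96).astype(float)
        perm = rng.permutation(96)
        df = pd.DataFrame(
            {"s": values[perm]}, index=[CHANNEL_LABELS[i] for i in perm]
        )
        path = tmp_path / "shuffled.tsv"
        df.to_csv(path, sep="\t", index_label="Somatic Mutation Type")
        (cat,) = sr.read_catalogue_table(path)
        assert np.array_equal(cat.values, values)

    @pytest.mark.parametrize("mutate", ["drop", "duplicate"])
    def test_missing_or_duplicate_channels_error(self, tmp_path, mutate):
        df = pd.DataFrame({"s": np.ones(96)}, index=list(CHANNEL_LABELS))
        if mutate == "drop":
            df = df.iloc[1:]
        else:
            df = pd.concat([df, df.iloc[[0]]])
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index_label="Somatic Mutation Type")
        with pytest.raises(ValueError, match="channel rows"):
            sr.read_catalogue_table(path)

    def test_frequency_scale_detection_and_invariants(self):
        freq = np.full(96, 1 / 96)
        cat = sr.MutationalCatalogue("f", freq, "frequencies")
        assert cat.as_frequencies() is cat
        with pytest.raises(ValueError, match="sum"):
            sr.MutationalCatalogue("bad", freq * 2, "frequencies")
        with pytest.raises(ValueError):
            sr.MutationalCatalogue("neg", -np.ones(96))


class TestSignatureMatrices:
    def test_toy_matrix_round_trip(self, tmp_path, fixture_dir):
        P = sr.read_signature_matrix(fixture_dir["signatures_plain"], "plain_matrix")
        assert P.names == ["Toy A", "Toy B"]
        path = tmp_path / "sig.tsv"
        sr.write_signature_matrix(P, path)
        P2 = sr.read_signature_matrix(path, "plain_matrix")
        assert np.array_equal(P.matrix, P2.matrix)

    def test_cosmic_v2_dialect_matches_plain(self, fixture_dir):
        plain = sr.read_signature_matrix(fixture_dir["signatures_plain"], "plain_matrix")
        cosmic = sr.read_signature_matrix(
            fixture_dir["signatures_cosmic_v2"], "cosmic_v2"
        )
        assert cosmic.names == plain.names
        assert np.allclose(cosmic.matrix, plain.matrix)

    def test_shuffled_rows_reordered(self, tmp_path, fixture_dir):
        df = pd.read_csv(fixture_dir["signatures_plain"], sep="\t", index_col=0)
        shuffled = df.sample(frac=1.0, random_state=5)
        path = tmp_path / "shuffled.tsv"
        shuffled.to_csv(path, sep="\t", index_label="Type")
        P = sr.read_signature_matrix(path, "plain_matrix")
        ref = sr.read_signature_matrix(fixture_dir["signatures_plain"], "plain_matrix")
        assert np.allclose(P.matrix, ref.matrix)

    def test_bad_column_sum_is_load_error(self, tmp_path):
        mat = np.zeros((96, 1))
        mat[:48, 0] = 0.5 / 48  # sums to 0.5
        df = pd.DataFrame(mat, index=list(CHANNEL_LABELS), columns=["Half"])
        path = tmp_path / "half.tsv"
        df.to_csv(path, sep="\t", index_label="Type")
        with pytest.raises(ValueError, match="Half"):
            sr.read_signature_matrix(path, "plain_matrix")

    def test_missing_file_error_names_path(self):
        with pytest.raises(FileNotFoundError, match="nope.tsv"):
            sr.read_signature_matrix("nope.tsv", "plain_matrix")
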