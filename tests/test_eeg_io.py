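"""EDF/CSV recording round-trips, PSQI tables, result bundles."""

import numpy as np
import pandas as pd
import pytest

from sleepalpha.eeg_io import (ResultBundle, read_psqi_table, read_recording,
                               recording_filename, write_psqi_table,
                               write_recording, write_results)
from sleepalpha.types import PSQIRecord, Recording


@pytest.fixture
def recording():
    rng = np.random.default_rng(0)
    samples = rng.normal(scale=20.0, size=(2, 512 * 10))
    return Recording(participant_id="P03", month=2, condition="closed",
                     fs=512.0, samples=samples)


class TestEDFRoundTrip:
    def test_samples_survive_within_quantization(self, recording, tmp_path):
        path = tmp_path / recording_filename(recording, "edf")
        write_recording(recording, path)
        back = read_recording(path)
        # 16-bit quantization over the physical range bounds the error
        rng_uv = np.abs(recording.samples).max() * 1.01
        q = 2 * rng_uv / 65535
        assert np.abs(back.samples - recording.samples).max() <= q
        assert back.fs == 512.0
        assert back.participant_id == "P03"
        assert back.month == 2 and back.condition == "closed"

    def test_explicit_range_clipping_refused(self, recording, tmp_path):
        from sleepalpha.eeg_io import write_recording_edf
        with pytest.raises(ValueError, match="clipping"):
            write_recording_edf(recording, tmp_path / "x.edf",
                                phys_range_uv=1.0)

    def test_non_integer_second_count_refused(self, tmp_path):
        rec = Recording("P01", 1, "open", 512.0,
                        np.zeros((2, 512 * 3 + 100)))
        with pytest.raises(ValueError, match="CSV"):
            write_recording(rec, tmp_path / "x.edf")


class TestCSVRoundTrip:
    def test_round_trip(self, recording, tmp_path):
        path = tmp_path / recording_filename(recording, "csv")
        write_recording(recording, path)
        back = read_recording(path)
        assert np.abs(back.samples - recording.samples).max() < 1e-5
        assert back.key == recording.key

    def test_missing_channel_rejected(self, recording, tmp_path):
        path = tmp_path / "P03_m2_closed.csv"
        write_recording(recording, path)
        df = pd.read_csv(path)
        df[df["channel"] != "FP2"].to_csv(path, index=False)
        with pytest.raises(ValueError, match="FP2"):
            read_recording(path)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_recording(tmp_path / "absent.csv")


class TestPSQITable:
    def _records(self):
        return [
            PSQIRecord("P01", 1, (1, 1, 1, 0, 0, 2, 1)),
            PSQIRecord("P02", 1, (3, 2, 3, 3, 2, 3, 3)),
        ]

    def test_round_trip(self, tmp_path):
        path = tmp_path / "psqi.tsv"
        write_psqi_table(self._records(), path)
        back = read_psqi_table(path)
        assert back == self._records()

    def test_consistent_row_accepted(self, tmp_path):
        path = tmp_path / "psqi.tsv"
        write_psqi_table([PSQIRecord("P01", 1, (1, 1, 1, 0, 0, 2, 1))], path)
        assert read_psqi_table(path)[0].total == 6

    def test_total_mismatch_names_row(self, tmp_path):
        path = tmp_path / "psqi.tsv"
        write_psqi_table(self._records(), path)
        df = pd.read_csv(path, sep="\t")
        df.loc[0, "psqi_total"] = 11
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="row 0"):
            read_psqi_table(path)

    def test_component_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "psqi.tsv"
        write_psqi_table(self._records(), path)
        df = pd.read_csv(path, sep="\t")
        df.loc[1, "psqi_c3"] = 5
        df.loc[1, "psqi_total"] = int(
            df.loc[1, [f"psqi_c{i}" for i in range(1, 8)]].sum())
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="0-3"):
            read_psqi_table(path)

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "psqi.tsv"
        path.write_text("")
        assert read_psqi_table(path) == []


class TestWriteResults:
    def _bundle(self):
        bp = pd.DataFrame([
            dict(participant="P01", month=1, condition="closed", band="LA",
                 component="raw", rel_power=0.07),
            dict(participant="P01", month=1, condition="open", band="LA",
                 component="raw", rel_power=0.05),
        ])
        empty = pd.DataFrame()
        return ResultBundle(band_power=bp, band_correlations=empty,
                            correlation_spectrum=empty, paired_tests=empty,
                            crossmonth_tests=empty,
                            metadata={"seed": 1})

    def test_deterministic_output(self, tmp_path):
        m1 = write_results(self._bundle(), tmp_path / "a")
        m2 = write_results(self._bundle(), tmp_path / "b")
        assert m1["files"] == m2["files"]

    def test_empty_bundle_writes_metadata_only(self, tmp_path):
        empty = pd.DataFrame()
        bundle = ResultBundle(band_power=empty, band_correlations=empty,
                              correlation_spectrum=empty, paired_tests=empty,
                              crossmonth_tests=empty, metadata={"seed": 0})
        manifest = write_results(bundle, tmp_path)
        assert list(manifest["files"]) == ["run_metadata.json"]

    def test_invalid_p_value_rejected(self, tmp_path):
        b = self._bundle()
        b.paired_tests = pd.DataFrame([dict(month=1, band="LA",
                                            component="raw", p=1.7)])
        with pytest.raises(ValueError, match="p"):
            write_results(b, tmp_path)
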