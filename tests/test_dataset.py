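"""Dataset handling: class mapping, segmentation, balancing, WFDB I/O."""

import os
import struct

import numpy as np
import pytest

import scatterbeat as sb
from scatterbeat.dataset import (CLASS_ORDER, SYMBOL_MAP, AamiClass,
                                 PacedRecordError)
from scatterbeat import wfdb_io


class TestSymbolMapping:
    @pytest.mark.parametrize("symbol,expected", [
        ("premature ventricular contraction", "V"),
        ("left bundle branch block beat", "N"),
        ("paced beat", "Q"),
        ("Atrial premature", "S"),
        ("fusion of ventricular and normal", "F"),
        ("V", "V"), ("L", "N"), ("A", "S"), ("F", "F"), ("/", "Q"),
        ("e", "N"), ("j", "N"), ("a", "S"), ("J", "S"), ("S", "S"),
        ("E", "V"), ("f", "Q"), ("Q", "Q"),
    ])
    def test_examples(self, symbol, expected):
        assert sb.map_annotation_symbol(symbol).value == expected

    def test_mapping_partitions_beat_vocabulary(self):
        """Every beat code maps, and the five classes partition the set."""
        groups = {c: [] for c in "NSVFQ"}
        for sym in SYMBOL_MAP:
            groups[sb.map_annotation_symbol(sym).value].append(sym)
        assert sum(len(g) for g in groups.values()) == len(SYMBOL_MAP) == 15
        assert sorted(groups["N"]) == ["L", "N", "R", "e", "j"]
        assert sorted(groups["S"]) == ["A", "J", "S", "a"]
        assert sorted(groups["V"]) == ["E", "V"]
        assert groups["F"] == ["F"]
        assert sorted(groups["Q"]) == ["/", "Q", "f"]

    def test_unknown_symbol_raises_with_symbol_in_message(self):
        with pytest.raises(ValueError, match="'!'"):
            sb.map_annotation_symbol("!")
        with pytest.raises(ValueError, match="sinus whatever"):
            sb.map_annotation_symbol("sinus whatever")


class TestSegmentation:
    def test_boundary_exact_window(self):
        sig = np.arange(300, dtype=float)
        beats = sb.segment_beats(sig, [99], ["N"])
        assert len(beats) == 1
        assert np.array_equal(beats[0].samples, sig[0:250])
        assert beats[0].r_index == 99

    def test_window_out_of_bounds_dropped(self):
        sig = np.zeros(300)
        assert sb.segment_beats(sig, [98], ["N"]) == []      # starts at -1
        assert sb.segment_beats(sig, [150], ["N"]) == []     # ends at 300
        assert len(sb.segment_beats(sig, [149], ["N"])) == 1  # ends at 299

    def test_q_beats_dropped(self):
        sig = np.zeros(300)
        beats = sb.segment_beats(sig, [99, 120], ["N", "Q"])
        assert len(beats) == 1
        assert beats[0].label is AamiClass.N

    def test_unsorted_r_peaks_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            sb.segment_beats(np.zeros(600), [200, 150], ["N", "N"])

    def test_samples_are_bit_exact_source_slices(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(size=1000)
        beats = sb.segment_beats(sig, [120, 400, 700], ["N", "V", "S"], "rec")
        for b, r in zip(beats, (120, 400, 700)):
            assert np.array_equal(b.samples, sig[r - 99:r + 151])
            assert not b.augmented


class TestBalancing:
    def test_plan_matches_policy_arithmetic(self):
        plan = sb.plan_balance({"N": 120, "S": 12, "V": 30, "F": 6}, 100)
        assert plan["N"] == {"keep": 100, "augment": 0}
        assert plan["S"] == {"keep": 12, "augment": 88}
        assert plan["F"] == {"keep": 6, "augment": 94}
        with pytest.raises(ValueError, match="empty"):
            sb.plan_balance({"N": 0}, 10)
        with pytest.raises(ValueError, match="positive"):
            sb.plan_balance({"N": 5}, 0)

    def _beats(self, counts, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for cls, n in counts.items():
            for _ in range(n):
                out.append(sb.Beat(rng.normal(size=250), AamiClass(cls)))
        return out

    def test_counts_exact_after_balancing(self):
        beats = self._beats({"N": 120, "S": 12, "V": 30, "F": 6})
        out = sb.augment_to_balance(beats, target_per_class=100, seed=1)
        assert len(out) == 400
        for cls in CLASS_ORDER:
            assert sum(1 for b in out if b.label.value == cls) == 100

    def test_majority_subsampled_without_noise(self):
        beats = self._beats({"N": 120, "S": 100, "V": 100, "F": 100})
        out = sb.augment_to_balance(beats, target_per_class=100, seed=1)
        originals = {b.samples.tobytes() for b in beats}
        for b in out:
            assert not b.augmented
            assert b.samples.tobytes() in originals

    def test_all_classes_at_target_is_identity(self):
        beats = self._beats({"N": 10, "S": 10, "V": 10, "F": 10})
        out = sb.augment_to_balance(beats, target_per_class=10, seed=5)
        assert len(out) == 40
        assert all(not b.augmented for b in out)
        for a, b in zip(beats, out):
            assert a is b  # same objects, same order

    def test_noise_moments(self):
        """Noise on augmented copies: mean 0, variance 0.05 within 3 SE."""
        base = sb.Beat(np.zeros(250), AamiClass.S)
        pad = self._beats({"N": 1, "V": 1, "F": 1})
        out = sb.augment_to_balance([base] + pad, target_per_class=400, seed=2)
        noise = np.concatenate([b.samples for b in out
                                if b.label is AamiClass.S and b.augmented])
        n = noise.size
        assert n >= 1e5 - 250
        se_mean = np.sqrt(0.05 / n)
        assert abs(noise.mean()) < 3 * se_mean
        se_var = 0.05 * np.sqrt(2.0 / (n - 1))
        assert abs(noise.var() - 0.05) < 3 * se_var

    def test_reproducible_given_seed(self):
        beats = self._beats({"N": 20, "S": 5, "V": 8, "F": 3})
        a = sb.augment_to_balance(beats, target_per_class=15, seed=7)
        b = sb.augment_to_balance(beats, target_per_class=15, seed=7)
        assert all(np.array_equal(x.samples, y.samples) for x, y in zip(a, b))


class TestCsvRoundtrip:
    def test_roundtrip(self, tmp_path):
        beats = sb.generate_dataset(3, seed=0)
        path = str(tmp_path / "beats.csv")
        sb.beats_to_csv(beats, path)
        back = sb.beats_from_csv(path)
        assert len(back) == len(beats)
        for a, b in zip(beats, back):
            assert np.allclose(a.samples, b.samples)
            assert a.label == b.label


class TestWfdb:
    def test_fixture_roundtrip_channel_selection(self, tmp_path):
        path = sb.write_wfdb_fixture(str(tmp_path), n_beats=8, seed=0)
        sig, r_peaks, labels = sb.load_wfdb_record(path)
        assert len(r_peaks) == 8
        assert [l.value for l in labels[:4]] == ["N", "S", "V", "F"]
        beats = sb.segment_beats(sig, r_peaks, labels, "synth100")
        assert len(beats) == 8
        # R-peak dominance survives quantization; jitter moves it <= 3 samples
        assert all(abs(b.samples.argmax() - 99) <= 3 for b in beats
                   if b.label in (AamiClass.N, AamiClass.S))

    def test_missing_lead_raises(self, tmp_path):
        path = sb.write_wfdb_fixture(str(tmp_path), n_beats=4, seed=0)
        with pytest.raises(ValueError, match="V1"):
            sb.load_wfdb_record(path, lead_name="V1")

    def test_paced_record_skip_signal(self, tmp_path):
        d = tmp_path / "107"
        with pytest.raises(PacedRecordError, match="107"):
            sb.load_wfdb_record(str(d))
        # exclusion can be disabled (file absence then surfaces instead)
        with pytest.raises(FileNotFoundError):
            sb.load_wfdb_record(str(d), exclude_paced=False)

    def test_non_beat_annotations_filtered(self, tmp_path):
        path = sb.write_wfdb_fixture(str(tmp_path), n_beats=5, seed=1)
        anns = wfdb_io.read_annotations(path)
        anns.append((anns[2][0] + 10, "+"))  # rhythm change marker
        wfdb_io.write_annotations(path, anns)
        _, r_peaks, _ = sb.load_wfdb_record(path)
        assert len(r_peaks) == 5

    def test_format_212_decoding_against_hand_packed_bytes(self, tmp_path):
        # two samples per 3 bytes: s0=100 -> (100, 0x0), s1=-200 -> 12-bit
        # 3896 -> (0xF, 56); byte1 packs high nibbles (s1 << 4 | s0)
        samples = [100, -200, -1, 2047]
        raw = bytes([100, 0xF0, 56, 0xFF, 0x7F, 0xFF])
        (tmp_path / "r212.dat").write_bytes(raw)
        (tmp_path / "r212.hea").write_text(
            "r212 2 360 2\nr212.dat 212 200(0)/mV 12 0 100 0 0 MLII\n"
            "r212.dat 212 200(0)/mV 12 0 -200 0 0 V5\n")
        sig, fs, names = wfdb_io.read_record(str(tmp_path / "r212"))
        assert fs == 360
        assert names == ["MLII", "V5"]
        flat = np.round(sig * 200).astype(int).reshape(-1)
        assert list(flat) == samples

    def test_annotation_skip_long_interval_roundtrip(self, tmp_path):
        anns = [(99, "N"), (500, "V"), (200000, "A")]  # gap >> 1023
        stem = str(tmp_path / "longgap")
        wfdb_io.write_annotations(stem, anns)
        assert wfdb_io.read_annotations(stem) == anns

    def test_physical_units_use_gain_and_baseline(self, tmp_path):
        sig = np.linspace(-1, 1, 50)[:, None]
        path = wfdb_io.write_record(str(tmp_path), "units", sig, 360.0,
                                    ["MLII"], gain=200.0, adc_zero=1024)
        back, _, _ = wfdb_io.read_record(path)
        assert np.allclose(back[:, 0], sig[:, 0], atol=1 / 200.0)
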