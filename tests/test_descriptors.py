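"""Descriptor-family tests, each checked against an independent oracle
coded directly from the defining formulas (loops, no shared code with the
vectorized implementation)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ppidiff as pp
from ppidiff.descriptors import (
    CTD_PROPERTIES,
    DescriptorError,
    compute_matrix,
    feature_names,
)
from ppidiff.seq_io import STANDARD_AA

sequences = st.text(alphabet=STANDARD_AA, min_size=2, max_size=60)


def record(seq, pid="p"):
    return pp.ProteinRecord(pid, seq)


# ---------------------------------------------------------------------------
# AAC / DPC
# ---------------------------------------------------------------------------

class TestAAC:
    def test_homopolymer(self):
        aac = pp.compute_aac(record("AAAA"))
        assert aac["AAC_A"] == 1.0
        assert sum(aac.values()) == pytest.approx(1.0)
        assert all(v == 0.0 for k, v in aac.items() if k != "AAC_A")

    def test_two_letter_mix(self):
        aac = pp.compute_aac(record("ACAC"))
        assert aac["AAC_A"] == 0.5 and aac["AAC_C"] == 0.5

    @given(sequences)
    @settings(max_examples=50, deadline=None)
    def test_components_sum_to_one(self, seq):
        assert sum(pp.compute_aac(record(seq)).values()) == pytest.approx(1.0)


class TestDPC:
    def test_homopolymer_single_component(self):
        dpc = pp.compute_dpc(record("AAA"))
        assert dpc["DPC_AA"] == 1.0
        assert sum(v != 0 for v in dpc.values()) == 1

    def test_overlapping_count(self):
        dpc = pp.compute_dpc(record("ACA"))
        assert dpc["DPC_AC"] == 0.5 and dpc["DPC_CA"] == 0.5

    def test_single_residue_rejected(self):
        with pytest.raises(DescriptorError, match="dipeptide"):
            pp.compute_dpc(record("A"))

    def test_not_reversal_invariant(self):
        assert pp.compute_dpc(record("AC"))["DPC_AC"] == 1.0
        assert pp.compute_dpc(record("CA"))["DPC_CA"] == 1.0

    @pytest.mark.parametrize("k", [1, 2, 5, 40])
    def test_alternating_sequence_exact_fraction(self, k):
        dpc = pp.compute_dpc(record("AC" * k))
        assert dpc["DPC_AC"] == k / (2 * k - 1)
        assert dpc["DPC_CA"] == (k - 1) / (2 * k - 1)

    @given(sequences)
    @settings(max_examples=100, deadline=None)
    def test_contract_on_random_sequences(self, seq):
        """400 components in [0, 1] summing to 1, matching direct counting."""
        dpc = pp.compute_dpc(record(seq))
        assert len(dpc) == 400
        values = np.array(list(dpc.values()))
        assert np.all((values >= 0) & (values <= 1))
        assert values.sum() == pytest.approx(1.0)
        # brute-force count of one dipeptide present in the sequence
        dp = seq[:2]
        count = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == dp)
        assert dpc[f"DPC_{dp}"] == pytest.approx(count / (len(seq) - 1))


# ---------------------------------------------------------------------------
# Moran autocorrelation
# ---------------------------------------------------------------------------

def moran_bruteforce(seq, values, d):
    """Literal transcription of the autocorrelation definition."""
    m = [values[a] for a in seq]
    n = len(m)
    mbar = sum(m) / n
    denom = sum((mi - mbar) ** 2 for mi in m) / n
    if denom == 0:
        return 0.0
    num = sum((m[i] - mbar) * (m[i + d] - mbar) for i in range(n - d)) / (n - d)
    return num / denom


class TestMoran:
    def test_constant_property_returns_zero(self):
        scale = pp.load_scale("Mutability")
        assert pp.compute_moran(record("AAAAA"), scale, 1) == 0.0

    def test_two_valued_alternating_matches_oracle(self):
        scale = pp.PropertyScale(
            "toy", {a: (1.0 if a == "A" else -1.0) for a in STANDARD_AA}
        )
        seq = "ACACAC"
        got = pp.compute_moran(record(seq), scale, 2)
        assert got == pytest.approx(moran_bruteforce(seq, scale.values, 2), rel=1e-12)

    def test_matches_oracle_over_all_lags(self, rng):
        seq = "".join(rng.choice(list(STANDARD_AA), size=40))
        values = dict(zip(STANDARD_AA, rng.normal(size=20)))
        scale = pp.PropertyScale("rand", values)
        for d in range(1, 31):
            got = pp.compute_moran(record(seq), scale, d)
            want = moran_bruteforce(seq, values, d)
            assert got == pytest.approx(want, rel=1e-12, abs=1e-12)

    def test_affine_rescaling_invariance(self, rng):
        seq = "".join(rng.choice(list(STANDARD_AA), size=50))
        base = dict(zip(STANDARD_AA, rng.normal(size=20)))
        shifted = {a: 3.7 * v - 11.0 for a, v in base.items()}
        for d in (1, 5, 13):
            assert pp.compute_moran(
                record(seq), pp.PropertyScale("a", base), d
            ) == pytest.approx(
                pp.compute_moran(record(seq), pp.PropertyScale("b", shifted), d),
                rel=1e-10,
            )

    def test_reversal_symmetry(self, rng):
        seq = "".join(rng.choice(list(STANDARD_AA), size=45))
        scale = pp.load_scale("Steric")
        for d in (1, 7, 20):
            assert pp.compute_moran(record(seq), scale, d) == pytest.approx(
                pp.compute_moran(record(seq[::-1]), scale, d), rel=1e-10
            )

    def test_lag_out_of_range(self):
        with pytest.raises(DescriptorError, match="lag"):
            pp.compute_moran(record("ACDE"), pp.load_scale("Polarity"), 4)


class TestMoranProfile:
    CONFIG = pp.DescriptorConfig(
        families=("MoranAuto",), moran_scales=("Mutability", "Steric")
    )

    def test_feature_count_and_naming(self, rng):
        seq = "".join(rng.choice(list(STANDARD_AA), size=60))
        profile = pp.compute_moran_profile(record(seq), self.CONFIG)
        assert len(profile) == 60  # 2 scales x 30 lags
        assert "MoranAuto_Mutability27" in profile

    def test_constant_sequence_all_zero(self):
        profile = pp.compute_moran_profile(record("A" * 60), self.CONFIG)
        assert all(v == 0.0 for v in profile.values())

    def test_short_protein_raises_and_is_excluded_from_matrix(self, caplog):
        short = record("ACDEF", "short")
        with pytest.raises(DescriptorError, match="length"):
            pp.compute_moran_profile(short, self.CONFIG)
        ok = record("ACDEFGHIKL" * 6, "ok")
        matrix = compute_matrix([short, ok], self.CONFIG)
        assert list(matrix.index) == ["ok"]


# ---------------------------------------------------------------------------
# PAAC / APAAC (literal-formula oracles)
# ---------------------------------------------------------------------------

def _norm_table(raw):
    vals = [raw[a] for a in STANDARD_AA]
    mean = sum(vals) / 20
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 20)
    return {a: (raw[a] - mean) / sd for a in STANDARD_AA}


def paac_oracle(seq, lam, w):
    """Step-by-step transcription of the published PAAC formulas."""
    h1 = _norm_table(pp.load_scale("PAACHydrophobicity").values)
    h2 = _norm_table(pp.load_scale("PAACHydrophilicity").values)
    mass = _norm_table(pp.load_scale("SideChainMass").values)
    n = len(seq)
    theta = []
    for d in range(1, lam + 1):
        total = 0.0
        for i in range(n - d):
            a, b = seq[i], seq[i + d]
            total += (
                (h1[a] - h1[b]) ** 2 + (h2[a] - h2[b]) ** 2 + (mass[a] - mass[b]) ** 2
            ) / 3.0
        theta.append(total / (n - d))
    denom = 1.0 + w * sum(theta)
    freqs = [seq.count(a) / n for a in STANDARD_AA]
    return [f / denom for f in freqs] + [w * t / denom for t in theta]


def apaac_oracle(seq, lam, w):
    h1 = _norm_table(pp.load_scale("PAACHydrophobicity").values)
    h2 = _norm_table(pp.load_scale("PAACHydrophilicity").values)
    n = len(seq)
    tau = []
    for d in range(1, lam + 1):
        tau.append(sum(h1[seq[i]] * h1[seq[i + d]] for i in range(n - d)) / (n - d))
        tau.append(sum(h2[seq[i]] * h2[seq[i + d]] for i in range(n - d)) / (n - d))
    denom = 1.0 + w * sum(tau)
    freqs = [seq.count(a) / n for a in STANDARD_AA]
    return [f / denom for f in freqs] + [w * t / denom for t in tau]


FIXED_30MER = "MKVLAACDEFGHIKWWLMNPQRSTVYEDKH"


class TestPseudoComposition:
    def test_lambda_zero_equals_aac(self):
        config = pp.DescriptorConfig(paac_lambda=0)
        rec = record(FIXED_30MER)
        aac = list(pp.compute_aac(rec).values())
        assert list(pp.compute_paac(rec, config).values()) == pytest.approx(aac)
        assert list(pp.compute_apaac(rec, config).values()) == pytest.approx(aac)

    @pytest.mark.parametrize("lam", [1, 5, 10])
    def test_paac_matches_literal_oracle(self, lam):
        config = pp.DescriptorConfig(paac_lambda=lam, paac_weight=0.05)
        got = list(pp.compute_paac(record(FIXED_30MER), config).values())
        want = paac_oracle(FIXED_30MER, lam, 0.05)
        assert got == pytest.approx(want, rel=1e-12)
        assert len(got) == 20 + lam
        assert min(got) >= 0.0

    @pytest.mark.parametrize("lam", [1, 5, 10])
    def test_apaac_matches_literal_oracle(self, lam):
        config = pp.DescriptorConfig(paac_lambda=lam, paac_weight=0.05)
        got = list(pp.compute_apaac(record(FIXED_30MER), config).values())
        assert got == pytest.approx(apaac_oracle(FIXED_30MER, lam, 0.05), rel=1e-12)
        assert len(got) == 20 + 2 * lam

    @given(st.text(alphabet=STANDARD_AA, min_size=12, max_size=60))
    @settings(max_examples=30, deadline=None)
    def test_components_sum_to_one(self, seq):
        config = pp.DescriptorConfig(paac_lambda=10)
        assert sum(pp.compute_paac(record(seq), config).values()) == pytest.approx(
            1.0, abs=1e-12
        )
        assert sum(pp.compute_apaac(record(seq), config).values()) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_too_short_sequence_raises(self):
        with pytest.raises(DescriptorError, match="paac_lambda"):
            pp.compute_paac(record("ACDEF"), pp.DescriptorConfig(paac_lambda=10))


# ---------------------------------------------------------------------------
# CTD
# ---------------------------------------------------------------------------

def ctd_oracle(seq):
    """Per-definition CTD computation from the class tables."""
    n = len(seq)
    out = {}
    for prop, classes in CTD_PROPERTIES.items():
        cls = [next(c for c, letters in enumerate(classes, 1) if a in letters)
               for a in seq]
        for c in (1, 2, 3):
            out[f"CTD_{prop}_C_{c}"] = cls.count(c) / n
        for c1, c2 in ((1, 2), (1, 3), (2, 3)):
            count = sum(
                1
                for i in range(n - 1)
                if {cls[i], cls[i + 1]} == {c1, c2}
            )
            out[f"CTD_{prop}_T_{c1}{c2}"] = count / (n - 1)
        for c in (1, 2, 3):
            positions = [i + 1 for i, x in enumerate(cls) if x == c]
            for pct in (1, 25, 50, 75, 100):
                key = f"CTD_{prop}_D_{c}_{pct}"
                if not positions:
                    out[key] = 0.0
                else:
                    k = max(1, math.ceil(pct / 100 * len(positions)))
                    out[key] = positions[k - 1] / n * 100.0
    return out


class TestCTD:
    def test_single_class_sequence(self):
        # A, L, F, ... are all "buried" in the solvent-accessibility alphabet
        ctd = pp.compute_ctd(record("ALFCGIVW"))
        assert ctd["CTD_SolventAccessibility_C_1"] == 1.0
        assert ctd["CTD_SolventAccessibility_C_2"] == 0.0
        assert ctd["CTD_SolventAccessibility_T_12"] == 0.0
        assert ctd["CTD_SolventAccessibility_T_13"] == 0.0

    def test_composition_partition_identity(self, rng):
        seq = "".join(rng.choice(list(STANDARD_AA), size=37))
        ctd = pp.compute_ctd(record(seq))
        for prop in CTD_PROPERTIES:
            total = sum(ctd[f"CTD_{prop}_C_{c}"] for c in (1, 2, 3))
            assert total == pytest.approx(1.0)

    def test_fixed_20mer_matches_oracle(self):
        seq = "MKVLAACDEFGHIKWWLMNP"
        assert pp.compute_ctd(record(seq)) == pytest.approx(ctd_oracle(seq))

    def test_class_alphabets_partition_the_alphabet(self):
        for prop, classes in CTD_PROPERTIES.items():
            joined = "".join(classes)
            assert sorted(joined) == sorted(STANDARD_AA), prop


# ---------------------------------------------------------------------------
# Full schema
# ---------------------------------------------------------------------------

class TestComputeAll:
    def test_aac_dpc_schema_has_420_features(self):
        config = pp.DescriptorConfig(families=("AAC", "DPC"))
        vec = pp.compute_all(record("ACDEFGHIKL"), config)
        assert len(vec.features) == 420

    def test_schema_consistent_across_proteins(self, rng):
        config = pp.DescriptorConfig()
        seqs = ["".join(rng.choice(list(STANDARD_AA), size=70)) for _ in range(2)]
        v1 = pp.compute_all(record(seqs[0], "a"), config)
        v2 = pp.compute_all(record(seqs[1], "b"), config)
        assert v1.names() == v2.names()
        assert v1.schema_id == v2.schema_id
        assert list(v1.names()) == feature_names(config)

    def test_dpc_only_homopolymer(self):
        vec = pp.compute_all(record("AAA"), pp.DescriptorConfig(families=("DPC",)))
        nonzero = {k: v for k, v in vec.features.items() if v != 0}
        assert nonzero == {"DPC_AA": 1.0}

    def test_default_schema_size(self):
        # 20 AAC + 400 DPC + 8*30 Moran + 30 PAAC + 40 APAAC + 147 CTD
        assert len(feature_names(pp.DescriptorConfig())) == 877

    def test_all_values_finite(self, rng):
        seq = "".join(rng.choice(list(STANDARD_AA), size=80))
        vec = pp.compute_all(record(seq), pp.DescriptorConfig())
        assert np.all(np.isfinite(vec.as_array()))
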