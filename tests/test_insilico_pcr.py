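"""Binding-site search, amplicon arithmetic, pools, specificity, hybrids."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodekit.errors import BarcodeKitError
from barcodekit.insilico_pcr import (
    PCRParams,
    find_binding_sites,
    infer_maternal_parent,
    predict_amplicons,
    predict_pool,
    specificity_matrix,
)
from barcodekit.marker_design import MarkerPair, PrimerCandidate
from barcodekit.seqio import revcomp


def rng_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestBindingSites:
    def test_exact_substring_found_at_position(self):
        rng = np.random.default_rng(1)
        template = rng_seq(rng, 60)
        primer = template[10:30]
        sites = [s for s in find_binding_sites(primer, template)
                 if s.strand == "plus"]
        assert [(s.start, s.mismatches) for s in sites] == [(10, 0)]

    def test_absent_primer_no_sites(self):
        assert find_binding_sites("ACGTACGTACGTACGTACGT", "T" * 60) == []

    def test_internal_mismatch_tolerated_but_not_in_clamp(self):
        rng = np.random.default_rng(2)
        template = rng_seq(rng, 60)
        primer = list(template[20:40])
        primer[5] = "ACGT"[("ACGT".index(primer[5]) + 1) % 4]  # internal
        p_internal = "".join(primer)
        params = PCRParams(max_mismatch=1)
        plus = [s for s in find_binding_sites(p_internal, template, params=params)
                if s.strand == "plus"]
        assert any(s.start == 20 and s.mismatches == 1 for s in plus)
        primer = list(template[20:40])
        primer[-2] = "ACGT"[("ACGT".index(primer[-2]) + 1) % 4]  # in 3' clamp
        p_clamp = "".join(primer)
        plus = [s for s in find_binding_sites(p_clamp, template, params=params)
                if s.strand == "plus" and s.start == 20]
        assert plus == []

    def test_template_n_never_matches(self):
        template = "AAAAANAAAAAAAAAAAAAAAAAAA"
        primer = "AAAAANAAAAAAAAAAAAAA"
        assert all(s.start != 0 for s in find_binding_sites(primer, template))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_zero_mismatch_equals_naive_substring_scan(self, seed):
        rng = np.random.default_rng(seed)
        template = rng_seq(rng, 80)
        primer = rng_seq(rng, 6)
        plus = {s.start for s in find_binding_sites(primer, template,
                                                    params=PCRParams(clamp=3))
                if s.strand == "plus"}
        naive = {i for i in range(len(template) - 5)
                 if template[i:i + 6] == primer}
        assert plus == naive


class TestAmplicons:
    def test_product_length_arithmetic(self):
        rng = np.random.default_rng(3)
        template = rng_seq(rng, 100)
        fwd = template[10:30]
        rev = revcomp(template[70:90])
        amps = predict_amplicons(fwd, rev, template)
        assert [a.product_length for a in amps] == [89 - 10 + 1]

    def test_strand_symmetry_on_reverse_complement(self):
        rng = np.random.default_rng(4)
        template = rng_seq(rng, 150)
        fwd = template[5:25]
        rev = revcomp(template[100:120])
        lengths = [a.product_length for a in predict_amplicons(fwd, rev, template)]
        # on the reverse-complement template the primer roles swap
        mirrored = [a.product_length
                    for a in predict_amplicons(rev, fwd, revcomp(template))]
        assert lengths == mirrored

    def test_pool_reveals_cross_binding_band(self):
        rng = np.random.default_rng(5)
        template = rng_seq(rng, 400)
        f_outer = template[10:30]
        f_inner = template[120:140]  # a second forward-binding primer
        rev = revcomp(template[350:370])
        lengths = sorted(a.product_length for a in predict_pool(
            {"fo": f_outer, "fi": f_inner, "r": rev}, template))
        assert lengths == [369 - 120 + 1, 369 - 10 + 1]


def marker_for(template, name, target, f_span, r_span):
    fwd = PrimerCandidate(f"{name}_F", "F", template[f_span[0]:f_span[1]],
                          f_span, 60.0, True)
    rev = PrimerCandidate(f"{name}_R", "R",
                          revcomp(template[r_span[0]:r_span[1]]), r_span, 60.0,
                          True)
    return MarkerPair(name, fwd, rev, target, r_span[1] - f_span[0], 65)


class TestSpecificityAndHybrids:
    def test_universal_primer_bands_everywhere(self):
        rng = np.random.default_rng(6)
        core = rng_seq(rng, 300)
        # same primer sites in every species, variable middle
        templates = {}
        species = {}
        for i in range(3):
            mid = rng_seq(rng, 100)
            templates[f"s{i}"] = core[:50] + mid + core[250:]
            species[f"s{i}"] = f"sp{i}"
        m = marker_for(templates["s0"], "uni", "sp0", (5, 25), (180, 200))
        # place reverse primer inside the conserved tail instead
        fwd = PrimerCandidate("uni_F", "F", core[5:25], (5, 25), 60.0, True)
        rev = PrimerCandidate("uni_R", "R", revcomp(core[260:280]), (260, 280),
                              60.0, True)
        m = MarkerPair("uni", fwd, rev, "sp0", 0, 65)
        sm = specificity_matrix([m], templates, species)
        for sid in templates:
            assert len(sm.bands("uni", sid)) == 1

    def test_empty_inputs_rejected(self):
        with pytest.raises(BarcodeKitError):
            specificity_matrix([], {}, {})

    def test_maternal_inference_requires_unique_band(self):
        rng = np.random.default_rng(7)
        tA = rng_seq(rng, 300)
        tB = rng_seq(rng, 300)
        mA = marker_for(tA, "mA", "A", (10, 30), (200, 220))
        mB = marker_for(tB, "mB", "B", (10, 30), (200, 220))
        sp, bands = infer_maternal_parent(tA, {"A": mA, "B": mB})
        assert sp == "A"
        sp, bands = infer_maternal_parent(tB, {"A": mA, "B": mB})
        assert sp == "B"
        unrelated = rng_seq(rng, 300)
        sp, bands = infer_maternal_parent(unrelated, {"A": mA, "B": mB})
        assert sp is None and all(v == 0 for v in bands.values())
        chimera = tA[:250] + tB  # both markers amplify -> inconclusive
        sp, _ = infer_maternal_parent(chimera, {"A": mA, "B": mB})
        assert sp is None
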