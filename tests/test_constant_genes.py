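import numpy as np
import pytest

from conftest import random_dna
from igloci.constant_genes import (
    Defect,
    GeneConfig,
    SearchParams,
    chain_exons,
    detect_exon_defects,
    find_constant_genes,
    translated_search,
)
from igloci.seqio import GenomicSequence, Interval, reverse_complement, translate
from igloci.synthetic_locus import (
    PREFERRED_CODON,
    SimConfig,
    generate_locus,
    reverse_translate,
)
from igloci.templates import IsotypeTemplate, default_templates

QUERY = default_templates()["mu"].protein("CH2")  # 100 aa synthetic domain


class TestTranslatedSearch:
    def test_exact_planted_query_found_with_exact_interval(self, rng):
        exon = reverse_translate(QUERY)
        left = random_dna(rng, 1000)
        # frame +2 on the plus strand
        seq = GenomicSequence("s", left + "AT" + exon + random_dna(rng, 1000))
        hits = translated_search(seq, QUERY)
        assert hits
        top = hits[0]
        assert top.percent_identity == 100.0
        assert (top.interval.start, top.interval.end) == (1002, 1002 + len(exon))
        assert top.interval.strand == "+"

    def test_minus_strand_query_found(self, rng):
        exon = reverse_translate(QUERY)
        seq = GenomicSequence(
            "s", random_dna(rng, 500) + reverse_complement(exon) + random_dna(rng, 500)
        )
        top = translated_search(seq, QUERY)[0]
        assert top.interval.strand == "-"
        assert (top.interval.start, top.interval.end) == (500, 500 + len(exon))

    def test_mutated_query_recovered_with_bounded_identity(self):
        # ~10% random codon substitutions: identity lands in [85, 95]
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            protein = list(QUERY)
            n_mut = len(protein) // 10
            sites = rng.choice(len(protein), n_mut, replace=False)
            alphabet = sorted(PREFERRED_CODON)
            for i in sites:
                protein[i] = alphabet[int(rng.integers(0, 20))]
            exon = reverse_translate("".join(protein))
            seq = GenomicSequence(
                "s", random_dna(rng, 800) + exon + random_dna(rng, 800)
            )
            hits = translated_search(seq, QUERY)
            assert hits
            assert 85.0 - 3 <= hits[0].percent_identity <= 95.0 + 3

    def test_absent_query_gives_no_hits(self):
        rng = np.random.default_rng(77)
        seq = GenomicSequence("s", random_dna(rng, 5000))
        assert translated_search(seq, QUERY) == []

    def test_short_query_refused(self, random_scaffold):
        with pytest.raises(ValueError):
            translated_search(random_scaffold, "MKV")


def _sim_c(seed, defects=(), isotypes=("mu", "gamma")):
    cfg = SimConfig(
        seed=seed,
        n_v=0,
        n_d=0,
        n_j=0,
        c_isotypes=isotypes,
        c_exon_defects=defects,
        include_delta_remnant=True,
        intergenic_bounds=(200, 400),
    )
    return generate_locus(cfg)


class TestChaining:
    def test_planted_mu_gene_is_intact_with_six_exons_in_order(self):
        seq, truth = _sim_c(0, isotypes=("mu",))
        models = find_constant_genes(seq, default_templates())
        mu = next(m for m in models if m.isotype == "mu")
        assert mu.status == "intact"
        assert [role for role, _ in mu.exons] == ["CH1", "CH2", "CH3", "CH4", "TM1", "TM2"]
        t = next(t for t in truth if t.kind == "C" and t.isotype == "mu")
        assert [(r, iv.start, iv.end) for r, iv in mu.exons] == [
            (r, iv.start, iv.end) for r, iv in t.exons
        ]

    def test_single_domain_without_gap_excuse_is_remnant(self):
        seq, _ = _sim_c(1, isotypes=("mu",))
        models = find_constant_genes(seq, default_templates())
        delta = next(m for m in models if m.isotype == "delta")
        assert delta.status == "remnant"
        assert len(delta.exons) == 1 and delta.exons[0][0] == "CH3"

    def test_exon_missing_inside_n_run_gives_partial_with_gap_defect(self, rng):
        template = default_templates()["gamma"]
        introns = [random_dna(rng, 200) for _ in range(4)]
        parts = [random_dna(rng, 500)]
        roles = template.roles
        for k, role in enumerate(roles):
            if role == "CH2":
                parts.append("N" * 5000)  # the exon's expected span is a gap
            else:
                parts.append(reverse_translate(template.protein(role)))
            if k < len(roles) - 1:
                parts.append(introns[k % 4])
        parts.append(random_dna(rng, 500))
        seq = GenomicSequence("s", "".join(parts))
        hits = {
            role: translated_search(seq, protein) for role, protein in template.exons
        }
        models = chain_exons(hits, template, seq, GeneConfig(intron_bounds=(80, 10_000)))
        assert len(models) == 1
        m = models[0]
        assert m.status == "partial"
        assert m.exon_defects.get("CH2") == ["missing_due_to_gap"]


class TestDefectDetection:
    TEMPLATE = QUERY  # 100 codons

    def _planted(self, dna, rng):
        left = random_dna(rng, 300)
        seq = GenomicSequence("s", left + dna + random_dna(rng, 300))
        exon = Interval("s", 300, 300 + len(dna), "+")
        return seq, exon

    def test_clean_exon_has_no_defects(self, rng):
        seq, exon = self._planted(reverse_translate(self.TEMPLATE), rng)
        assert detect_exon_defects(seq, exon, self.TEMPLATE) == []

    def test_premature_stop_position_from_codon_index(self, rng):
        # stop planted at codon 40 (1-based) of 100 -> nt 118..120
        dna = reverse_translate(self.TEMPLATE)
        dna = dna[: 3 * 39] + "TAG" + dna[3 * 39 + 3 :]
        seq, exon = self._planted(dna, rng)
        defects = detect_exon_defects(seq, exon, self.TEMPLATE)
        assert defects == [Defect("premature_stop", 118, 120)]

    def test_stop_in_final_tail_is_not_premature(self, rng):
        dna = reverse_translate(self.TEMPLATE)
        ci = len(self.TEMPLATE) - 2  # inside the final 5%
        dna = dna[: 3 * ci] + "TAA" + dna[3 * ci + 3 :]
        seq, exon = self._planted(dna, rng)
        assert detect_exon_defects(seq, exon, self.TEMPLATE) == []

    def test_single_a_insertion_reported_as_frameshift(self, rng):
        # codon 51 encodes Q (CAG) so the inserted A cannot silently
        # recreate the original residue; position 151 = 3*50 + 1
        assert self.TEMPLATE[50] == "Q"
        dna = reverse_translate(self.TEMPLATE)
        q = 3 * 50
        dna = dna[:q] + "A" + dna[q:]
        seq, exon = self._planted(dna, rng)
        defects = detect_exon_defects(seq, exon, self.TEMPLATE)
        assert defects == [Defect("frameshift_insertion", 151, 151)]

    def test_single_base_deletion_reported_as_frameshift(self, rng):
        dna = reverse_translate(self.TEMPLATE)
        q = 3 * 49
        dna = dna[:q] + dna[q + 1 :]
        seq, exon = self._planted(dna, rng)
        defects = detect_exon_defects(seq, exon, self.TEMPLATE)
        assert defects == [Defect("frameshift_deletion", 148, 148)]

    def test_defect_position_round_trips_to_a_stop_codon(self, rng):
        dna = reverse_translate(self.TEMPLATE)
        dna = dna[: 3 * 24] + "TGA" + dna[3 * 24 + 3 :]
        seq, exon = self._planted(dna, rng)
        (d,) = detect_exon_defects(seq, exon, self.TEMPLATE)
        codon = seq.residues[exon.start + d.start - 1 : exon.start + d.end]
        assert translate(codon) == "*"
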