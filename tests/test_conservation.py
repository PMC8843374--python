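"""1D/3D conservation calls, discrepancy stars, domain filter, summaries."""

import pandas as pd
import pytest

from kac3d.conservation import (
    ConservationCall,
    DomainDefinition,
    SiteAnnotation,
    build_sequence_msa,
    call_site_1d,
    call_site_3d,
    classify_discrepancy,
    domain_present,
    load_site_table,
    matrix_cell,
    packaged_domains,
    packaged_sites,
    summarize_conservation,
)
from kac3d.pairalign import flexible_align


def _site(residue=25, protein="target"):
    return SiteAnnotation(protein, residue, frozenset({"KAT:YiaC"}))


@pytest.fixture(scope="module")
def demo_alignments(demo_family):
    target = demo_family.target.chains[0]
    return {
        m.entry_id: flexible_align(target, m.chains[0], homolog_id=m.entry_id)
        for m in demo_family.homologs
    }


@pytest.fixture(scope="module")
def clean_alignments(clean_family):
    target = clean_family.target.chains[0]
    return {
        m.entry_id: flexible_align(target, m.chains[0], homolog_id=m.entry_id)
        for m in clean_family.homologs
    }


class TestCallSite3d:
    def test_aligned_lysine_conserved_no_flags(self, clean_family, clean_alignments):
        alns = clean_alignments
        for aln in alns.values():
            for residue in clean_family.spec.sites:
                call = call_site_3d(_site(residue), aln)
                assert call.conserved_3d is True
                assert not call.rescue_flag and not call.disorder_flag
                assert call.aligned_residue[0] == "K"

    def test_substituted_not_conserved(self, demo_alignments):
        # homolog 3 carries R at site 25
        alns = demo_alignments
        call = call_site_3d(_site(25), alns["syn003"])
        assert call.conserved_3d is False
        assert call.positive_substitution is True

    def test_rescue_fires_for_shifted_lysine(self, demo_alignments):
        # homolog 4: lysine moved +2 in sequence, kept in place in space
        alns = demo_alignments
        call = call_site_3d(_site(55), alns["syn004"])
        assert call.conserved_3d is True and call.rescue_flag is True

    def test_rescue_never_fires_on_aligned_lysine(
        self, clean_family, demo_family, clean_alignments, demo_alignments
    ):
        for family, alns in ((clean_family, clean_alignments), (demo_family, demo_alignments)):
            for aln in alns.values():
                for residue in family.spec.sites:
                    call = call_site_3d(_site(residue), aln)
                    if call.aligned_residue and call.aligned_residue[0] == "K":
                        assert not call.rescue_flag

    def test_disorder_flag_from_declared_sequence(self, demo_alignments):
        # homolog 6: loop around site 55 deleted from coordinates
        alns = demo_alignments
        call = call_site_3d(_site(55), alns["syn006"])
        assert call.conserved_3d is True and call.disorder_flag is True
        assert call.aligned_residue is None

    def test_displaced_lysine_not_conserved(self, demo_alignments):
        # homolog 5: loop carrying site 25 moved away in space
        alns = demo_alignments
        call = call_site_3d(_site(25), alns["syn005"])
        assert call.conserved_3d is False

    def test_site_not_in_target_errors(self, clean_alignments):
        alns = clean_alignments
        with pytest.raises(ValueError, match="not found"):
            call_site_3d(_site(999), next(iter(alns.values())))


class TestCallSite1d:
    def test_lysine_column(self):
        assert call_site_1d(_site(2), "AKC", "AKC", 2) is True

    def test_gap_column(self):
        assert call_site_1d(_site(2), "AKC", "A-C", 2) is False

    def test_substitution_column(self):
        assert call_site_1d(_site(2), "AKC", "ARC", 2) is False

    def test_gapped_target_row(self):
        assert call_site_1d(_site(2), "A-KC", "AQKC", 2) is True

    def test_position_beyond_row_errors(self):
        with pytest.raises(ValueError):
            call_site_1d(_site(9), "AKC", "AKC", 9)

    def test_star_msa_columns_match_pairwise(self, demo_family):
        target_seq = demo_family.target.chains[0].seqres_sequence
        rows = build_sequence_msa(
            "t", target_seq, {m.entry_id: m.chains[0].seqres_sequence for m in demo_family.homologs}
        )
        assert rows["t"] == target_seq
        assert all(len(v) == len(target_seq) for v in rows.values())


class TestDiscrepancy:
    @pytest.mark.parametrize(
        "c1d,c3d,label",
        [
            (True, False, "open_star"),
            (False, True, "filled_star"),
            (True, True, "agree"),
            (False, False, "agree"),
        ],
    )
    def test_table(self, c1d, c3d, label):
        call = ConservationCall(site=_site(), homolog_id="h")
        call.conserved_1d = c1d
        call.conserved_3d = c3d
        assert classify_discrepancy(call) == label

    def test_missing_field_errors(self):
        call = ConservationCall(site=_site(), homolog_id="h")
        call.conserved_3d = True
        with pytest.raises(ValueError):
            classify_discrepancy(call)

    def test_labels_partition_family_calls(self, demo_family, demo_alignments):
        alns = demo_alignments
        n = 0
        counts = {"agree": 0, "open_star": 0, "filled_star": 0}
        for aln in alns.values():
            for residue in demo_family.spec.sites:
                call = call_site_3d(_site(residue), aln)
                call.conserved_1d = call.conserved_3d if not call.rescue_flag else False
                counts[classify_discrepancy(call)] += 1
                n += 1
        assert sum(counts.values()) == n


class TestDomainPresent:
    def test_full_coverage(self, clean_alignments):
        alns = clean_alignments
        dom = DomainDefinition("target", "D1", ((1, 40),))
        assert domain_present(dom, next(iter(alns.values()))) is True

    def test_absent_domain(self, demo_alignments):
        """The disordered-loop family member still covers its domains, so
        build a truncated alignment by restricting correspondence."""
        alns = demo_alignments
        aln = alns["syn001"]
        import copy

        chopped = copy.copy(aln)
        chopped.correspondence = [(t, h) for t, h in aln.correspondence if t > 40]
        dom = DomainDefinition("target", "D1", ((1, 40),))
        assert domain_present(dom, chopped) is False

    def test_half_coverage_thresholds(self, clean_alignments):
        """50% coverage fails at threshold 0.7 and passes at 0.4
        (direct-count oracle by construction)."""
        alns = clean_alignments
        aln = next(iter(alns.values()))
        import copy

        dom = DomainDefinition("target", "D1", ((1, 40),))
        half = copy.copy(aln)
        covered = [t for t, _ in aln.correspondence if 1 <= t <= 40]
        keep = set(covered[: len(covered) // 2])
        half.correspondence = [
            (t, h) for t, h in aln.correspondence if t > 40 or t in keep
        ]
        n_target = 40
        frac = len(keep) / n_target
        assert domain_present(dom, half, coverage_threshold=0.7) is (frac >= 0.7)
        assert domain_present(dom, half, coverage_threshold=0.4) is (frac >= 0.4)
        assert frac < 0.7 and frac >= 0.4

    def test_empty_domain_errors(self, clean_alignments):
        alns = clean_alignments
        dom = DomainDefinition("target", "empty", ((900, 950),))
        with pytest.raises(ValueError):
            domain_present(dom, next(iter(alns.values())))


class TestSummaries:
    def _call(self, hid, site, c3d, c1d=None, domain=True, rescue=False):
        call = ConservationCall(site=site, homolog_id=hid)
        call.conserved_3d = c3d
        call.conserved_1d = c3d if c1d is None else c1d
        call.rescue_flag = rescue
        classify_discrepancy(call)
        call.domain_present = domain
        return call

    def _meta(self, rows):
        return pd.DataFrame(
            rows,
            columns=["uniprot_id", "taxon_group", "percent_identity_to_target"],
        )

    def test_fraction_arithmetic(self):
        site = _site(25)
        calls = [
            self._call("h1", site, True),
            self._call("h2", site, True),
            self._call("h3", site, False),
            self._call("h4", site, False),
        ]
        meta = self._meta(
            [
                ("h1", "Gram-negative", 90.0),
                ("h2", "Gram-negative", 80.0),
                ("h3", "Gram-negative", 70.0),
                ("h4", "Eukaryote", 60.0),
            ]
        )
        summaries, matrix = summarize_conservation(calls, meta)
        by_group = {s.group: s for s in summaries}
        assert by_group["Gram-negative"].conserved == 2
        assert by_group["Gram-negative"].total == 3
        assert by_group["Gram-negative"].fraction == pytest.approx(2 / 3)
        assert by_group["Eukaryote"].fraction == 0.0
        # matrix ordered by percent identity, one row per homolog
        assert list(matrix["homolog_id"]) == ["h1", "h2", "h3", "h4"]

    def test_domain_filter_excludes_from_denominator(self):
        site = _site(25)
        calls = [
            self._call("h1", site, True),
            self._call("h2", site, False, domain=False),
        ]
        meta = self._meta([("h1", "Archaea", 90.0), ("h2", "Archaea", 50.0)])
        summaries, _ = summarize_conservation(calls, meta)
        assert summaries[0].total == 1

    def test_missing_metadata_errors(self):
        calls = [self._call("h1", _site(25), True)]
        with pytest.raises(ValueError, match="without metadata"):
            summarize_conservation(calls, self._meta([("other", "Archaea", 1.0)]))

    def test_matrix_cells(self):
        site = _site(25)
        assert matrix_cell(self._call("h", site, True)) == "dot"
        assert matrix_cell(self._call("h", site, True, c1d=False)) == "filled_star"
        assert matrix_cell(self._call("h", site, False, c1d=True)) == "open_star"
        assert matrix_cell(self._call("h", site, False, c1d=False)) == "blank"
        assert matrix_cell(self._call("h", site, True, rescue=True)) == "open_circle"


class TestSiteTables:
    def test_packaged_adk_sites_merge_to_six_lysines(self):
        """The acetylation-site table yields six distinct Adk lysines
        across the KAT and AcP mechanisms."""
        sites = [s for s in packaged_sites() if s.protein_id == "adk"]
        assert sorted({s.residue for s in sites}) == [136, 141, 145, 157, 192, 211]
        kat = {s.residue for s in sites if s.is_kat}
        acp = {s.residue for s in sites if s.is_acp}
        assert kat == {136}
        assert acp == {141, 145, 157, 192, 211}

    def test_packaged_tables_complete(self):
        sites = packaged_sites()
        by_protein = {}
        for s in sites:
            by_protein.setdefault(s.protein_id, set()).add(s.residue)
        assert by_protein["icd"] == {4, 12, 174, 177, 235, 265, 378}
        assert by_protein["katE"] == {56, 64}
        assert by_protein["fmt"] == {45, 46}
        assert by_protein["yaaA"] == {55}
        domains = packaged_domains()
        lid = next(d for d in domains if d.protein_id == "adk" and d.name == "LID")
        assert lid.ranges == ((122, 159),)
        assert lid.contains(136) and not lid.contains(192)

    def test_unknown_mechanism_errors(self):
        df = pd.DataFrame(
            [{"protein_id": "x", "residue": 1, "mechanisms": "Phospho"}]
        )
        with pytest.raises(ValueError, match="unknown mechanisms"):
            load_site_table(df)

    def test_empty_mechanism_set_errors(self):
        with pytest.raises(ValueError, match="empty mechanism"):
            SiteAnnotation("x", 1, frozenset())
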