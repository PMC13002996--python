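"""Per-CpG call accumulation, filters, fractions, regions and tracks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import landscape_from_states, run_pipeline
from sixbct.chemistry import ChemistryParams
from sixbct.dna import STATE_5MC
from sixbct.errors import InvalidInputError, InvalidParameterError
from sixbct.quant import (
    COUNT_COLS,
    MethylTable,
    accumulate_calls,
    aggregate_regions,
    filter_coverage,
    global_fractions,
    read_bed,
    site_fractions,
    write_coverage_bedgraph,
    write_methyl_bedgraph,
)
from sixbct.reference import Genome, make_genome
from sixbct.resolve import ResolvedRead


def table_from_counts(rows):
    """rows: {(chrom,pos,strand): (U,M,H,X)} -> MethylTable."""
    idx = pd.MultiIndex.from_tuples(sorted(rows),
                                    names=["chrom", "pos", "strand"])
    data = np.array([rows[k] for k in sorted(rows)])
    return MethylTable(pd.DataFrame(data, index=idx, columns=COUNT_COLS))


GENOME = Genome({"chr1": "ATTA" * 20 + "ACGT" + "CTTA" + "ATTA" * 19})
CPG_POS = 81   # the C of the single CpG (81, 82)
CPH_POS = 84   # a lone C followed by T


def read_at(start, states, genetic=None, strand="+"):
    genetic = genetic or GENOME.records["chr1"][start:start + len(states)]
    return ResolvedRead("r", genetic, states, chrom="chr1", start=start,
                        strand=strand)


class TestAccumulateCalls:
    def test_thirty_m_reads_give_coverage_thirty(self):
        # M lands on the CpG C at 81; U on the non-CpG C at 84
        reads = [read_at(77, "....M..U..") for _ in range(30)]
        table = accumulate_calls(reads, GENOME)
        assert table.df.loc[("chr1", CPG_POS, "+")].tolist() == [0, 30, 0, 0]
        assert table.coverage.loc[("chr1", CPG_POS, "+")] == 30
        # the non-CpG C call went to the QC counter, not to a site
        assert table.noncpg_counts["U"] == 30

    def test_read_with_no_call_contributes_nothing(self):
        reads = [read_at(77, "........")]
        table = accumulate_calls(reads, GENOME)
        assert table.n_sites == 0

    def test_out_of_bounds_read_skipped_with_warning(self):
        reads = [ResolvedRead("r", "A" * 30, "." * 30, chrom="chr1",
                              start=len(GENOME.records["chr1"]) - 10,
                              strand="+")]
        table = accumulate_calls(reads, GENOME)
        assert table.metadata.get("n_reads_skipped") == 1

    def test_minus_strand_read_maps_to_minus_site(self):
        # a '-' read's position j maps to top coordinate start + L - 1 - j;
        # j=2 with start=77, L=8 lands on 82, the bottom-strand CpG cytosine
        read = ResolvedRead("r", "N" * 8, "..M.....", chrom="chr1",
                            start=77, strand="-")
        table = accumulate_calls([read], GENOME)
        assert table.df.loc[("chr1", 82, "-")].tolist() == [0, 1, 0, 0]

    def test_mixture_recovers_even_split(self, small_genome, ideal_params):
        rng = np.random.default_rng(0)
        overrides = {}
        plus_cpg = small_genome.cpg_sites("chr1")["+"]
        chosen = rng.random(len(plus_cpg)) < 0.5
        overrides["chr1"] = {int(p): STATE_5MC
                             for p, c in zip(plus_cpg, chosen) if c}
        land = landscape_from_states(small_genome, overrides)
        out = run_pipeline(small_genome, land, ideal_params, 3000, seed=6)
        df = out["table"].df
        # restrict to plus-strand sites, where half the sites are 5mC
        plus = df[df.index.get_level_values("strand") == "+"]
        frac = plus["n_M"].sum() / (plus["n_U"] + plus["n_M"]).sum()
        n = int((plus["n_U"] + plus["n_M"]).sum())
        se = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) <= 4 * se


class TestFilterCoverage:
    def test_threshold_keeps_sites_at_or_above(self):
        t = table_from_counts({
            ("chr1", 10, "+"): (19, 0, 0, 0),
            ("chr1", 20, "+"): (20, 0, 0, 0),
            ("chr1", 30, "+"): (21, 0, 0, 0),
        })
        assert filter_coverage(t, 20).n_sites == 2

    def test_zero_threshold_is_identity(self):
        t = table_from_counts({("chr1", 10, "+"): (5, 1, 0, 0)})
        assert filter_coverage(t, 0).df.equals(t.df)

    def test_empty_table_stays_empty(self):
        assert filter_coverage(MethylTable.empty(), 20).n_sites == 0

    def test_negative_threshold_raises(self):
        with pytest.raises(InvalidParameterError):
            filter_coverage(MethylTable.empty(), -1)

    @given(st.lists(st.tuples(st.integers(0, 40), st.integers(0, 40)),
                    min_size=1, max_size=20),
           st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=50, deadline=None)
    def test_composition_equals_max(self, counts, a, b):
        rows = {("chr1", i * 10, "+"): (u, m, 0, 0)
                for i, (u, m) in enumerate(counts)}
        t = table_from_counts(rows)
        left = filter_coverage(filter_coverage(t, a), b)
        right = filter_coverage(t, max(a, b))
        assert left.df.equals(right.df)


class TestFractions:
    def test_arithmetic_example(self):
        t = table_from_counts({("chr1", 10, "+"): (15, 5, 0, 0)})
        fr = site_fractions(t)
        assert fr["pct_5mc"].iloc[0] == 25.0
        assert fr["pct_5hmc"].iloc[0] == 0.0

    def test_subtype_percentages_sum_to_hundred(self):
        rng = np.random.default_rng(1)
        rows = {("chr1", int(i), "+"): tuple(rng.integers(0, 30, 4))
                for i in range(50)}
        fr = site_fractions(table_from_counts(rows))
        ok = fr["subtype_denom"] > 0
        total = fr.loc[ok, ["pct_unmod", "pct_5mc", "pct_5hmc"]].sum(axis=1)
        assert np.allclose(total, 100.0)

    def test_all_x_site_excluded_from_globals(self):
        t = table_from_counts({("chr1", 10, "+"): (0, 0, 0, 12),
                               ("chr1", 20, "+"): (10, 10, 0, 0)})
        g = global_fractions(t)
        assert g["n_sites"] == 1
        assert g["pct_5mc"] == 50.0

    def test_ideal_5mc_control_fully_methylated(self, small_genome,
                                                ideal_params):
        plus_cpg = small_genome.cpg_sites("chr1")["+"]
        overrides = {"chr1": {int(p): STATE_5MC for p in plus_cpg}}
        land = landscape_from_states(small_genome, overrides)
        out = run_pipeline(small_genome, land, ideal_params, 800, seed=8)
        df = out["table"].df
        plus = df[df.index.get_level_values("strand") == "+"]
        assert plus["n_M"].sum() > 0
        assert plus["n_U"].sum() == 0 and plus["n_H"].sum() == 0


class TestAggregateRegions:
    def test_region_mean_of_site_fractions(self):
        t = table_from_counts({
            ("chr1", 10, "+"): (18, 2, 0, 0),   # 10%
            ("chr1", 20, "+"): (16, 4, 0, 0),   # 20%
            ("chr1", 30, "+"): (14, 6, 0, 0),   # 30%
        })
        agg = aggregate_regions(t, [("chr1", 0, 100, "enh")])
        assert agg["pct_5mc"].iloc[0] == pytest.approx(20.0)
        assert agg["n_cpgs"].iloc[0] == 3

    def test_empty_region_flagged(self):
        t = table_from_counts({("chr1", 10, "+"): (10, 0, 0, 0)})
        agg = aggregate_regions(t, [("chr2", 0, 100, "enh")])
        assert bool(agg["empty"].iloc[0])
        assert np.isnan(agg["pct_5mc"].iloc[0])

    def test_malformed_bed_reports_line(self, tmp_path):
        bad = tmp_path / "bad.bed"
        bad.write_text("chr1\t10\t100\nchr1\tfifty\t60\n")
        with pytest.raises(InvalidInputError, match="line 2"):
            read_bed(bad)


class TestTracks:
    def test_methyl_bedgraph_line_format(self, tmp_path):
        t = table_from_counts({("chr1", 100, "+"): (15, 5, 0, 0)})
        path = tmp_path / "m.bedGraph"
        write_methyl_bedgraph(t, path, "5mc")
        lines = path.read_text().splitlines()
        assert lines[1] == "chr1\t100\t101\t25"

    def test_coverage_cpm_normalisation(self, tmp_path):
        genome = Genome({"chr1": "A" * 1000})
        reads = []
        for i in range(1000):
            start = 500 if i < 100 else (i % 40) * 10
            reads.append(ResolvedRead(f"r{i}", "A" * 20, "." * 20,
                                      chrom="chr1", start=start, strand="+"))
        path = tmp_path / "cov.bedGraph"
        write_coverage_bedgraph(reads, genome, path, bin_size=10)
        wanted = [l for l in path.read_text().splitlines()
                  if l.startswith("chr1\t500\t")]
        # bin holding 100 of 1000 fragments -> 100/1000 * 1e6 = 1e5 CPM
        assert wanted and float(wanted[0].split("\t")[3]) == pytest.approx(1e5)

    def test_empty_table_header_only(self, tmp_path):
        path = tmp_path / "e.bedGraph"
        write_methyl_bedgraph(MethylTable.empty(), path)
        assert len(path.read_text().splitlines()) == 1
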