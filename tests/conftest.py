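"""Shared fixtures: small synthetic references and pipeline helpers."""

from __future__ import annotations

import numpy as np
import pytest

from sixbct.chemistry import (
    ChemistryParams,
    Molecule,
    SimulationConfig,
    convert_molecule,
    emit_readpair,
    simulate_run,
)
from sixbct.dna import STATE_NONE, seq_to_array
from sixbct.quant import accumulate_calls
from sixbct.readproc import ME2U, trim_pairs
from sixbct.reference import Genome, MethylLandscape, make_genome
from sixbct.resolve import place_reads, resolve_pairs


def landscape_from_states(genome: Genome, plus_states: dict[str, dict[int, int]]
                          ) -> MethylLandscape:
    """Landscape with every cytosine unmodified except explicit overrides.

    ``plus_states``: chrom -> {top-strand position: state code} overrides for
    the plus strand.
    """
    plus, minus = {}, {}
    for chrom, seq in genome.records.items():
        arr = seq_to_array(seq)
        p = np.full(len(seq), STATE_NONE, dtype=np.int8)
        m = np.full(len(seq), STATE_NONE, dtype=np.int8)
        p[arr == "C"] = 0
        m[arr == "G"] = 0
        for pos, st in plus_states.get(chrom, {}).items():
            p[pos] = st
        plus[chrom], minus[chrom] = p, m
    return MethylLandscape(plus, minus)


def run_pipeline(genome, landscape, params, n_fragments, seed,
                 dialect=ME2U, annotation=None, target="WG"):
    """simulate -> trim -> resolve -> place -> accumulate, returning stages."""
    cfg = SimulationConfig(
        genome=genome, landscape=landscape, annotation=annotation,
        target_mark=target, n_fragments=n_fragments, params=params,
        dialect=dialect, seed=seed,
    )
    result = simulate_run(cfg)
    trimmed, counts = trim_pairs(result.pairs, dialect)
    resolved = resolve_pairs(trimmed)
    placed = [r for r in place_reads(resolved, genome) if r.placed]
    table = accumulate_calls(placed, genome)
    return dict(pairs=result.pairs, counts=counts, resolved=resolved,
                placed=placed, table=table)


def single_molecule_pair(core: str, states: list[int], params=None,
                         dialect=ME2U, pad5: str = "", pad3: str = "",
                         seed: int = 0):
    """Emit one ideal-chemistry read pair for pad5+core+pad3 (pads unmodified).

    Padding characters must avoid C/G so they add no methylation channels.
    Returns (pair, full_seq, full_states).
    """
    params = params or ChemistryParams.ideal(read_length=80)
    seq = pad5 + core + pad3
    st = ([STATE_NONE] * len(pad5) + list(states) + [STATE_NONE] * len(pad3))
    # non-C positions are STATE_NONE regardless of what was passed
    full_states = np.array(
        [st[i] if seq[i] == "C" else STATE_NONE for i in range(len(seq))],
        dtype=np.int8)
    genome = Genome({"m": seq if len(seq) >= 200 else seq + "A" * 200})
    mol = Molecule("m", 0, len(seq), "+", mol_id="single")
    land = MethylLandscape(
        {"m": np.concatenate([full_states,
                              np.full(len(genome.records["m"]) - len(seq),
                                      STATE_NONE, dtype=np.int8)])},
        {"m": np.full(len(genome.records["m"]), STATE_NONE, dtype=np.int8)},
    )
    rng = np.random.default_rng(seed)
    orig, copy = convert_molecule(mol, genome, land, params, rng)
    pair = emit_readpair(mol, orig, copy, dialect, params, rng)
    return pair, seq, full_states


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    return make_genome(11, [30000], gc_fraction=0.42, cpg_enrichment=2.0)


@pytest.fixture(scope="session")
def ideal_params() -> ChemistryParams:
    return ChemistryParams.ideal(read_length=100, insert_length_mean=55,
                                 insert_length_sd=10)
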