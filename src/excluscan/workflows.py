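"""End-to-end convenience workflows over the simulation and screen modules."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simdata import (
    SelectionModel,
    apply_conjugation_selection,
    generate_reference,
    simulate_insertion_library,
    synthesize_reads,
)
from .tradis import (
    call_candidates,
    compute_insertion_index,
    run_screen,
    sites_from_library,
)

__all__ = ["simulate_and_score"]


def simulate_and_score(
    seed: int,
    n_genes: int = 50,
    n_mutants: int = 10_000,
    base_rate: float = 0.01,
    planted_gene: str | None = "orf_p001",
    effect: float = 20.0,
    error_rate: float = 0.0,
    depth_per_mutant: int = 10,
    tag: str = "CTGTCTCTTA",
    threshold: float = 5.0,
    through_reads: bool = True,
) -> pd.DataFrame:
    """Simulate a full insertion screen and return its candidate table.

    One ``seed`` drives the whole experiment (reference, library, selection,
    read synthesis) through independent spawned streams. With
    ``through_reads=True`` the insertion libraries are turned into junction
    reads which are then tag-trimmed and mapped back; otherwise the library
    site sets are scored directly.
    """
    streams = np.random.SeedSequence(seed).spawn(5)
    ref, ann = generate_reference(n_genes, seed=streams[0])
    lib = simulate_insertion_library(ref, n_mutants, seed=streams[1])
    effects = {planted_gene: effect} if planted_gene else {}
    model = SelectionModel(base_rate=base_rate, effects=effects)
    out = apply_conjugation_selection(lib, model, ann, seed=streams[2])

    if through_reads:
        reads_in = synthesize_reads(
            lib, ref, tag=tag, error_rate=error_rate,
            depth_per_mutant=depth_per_mutant, seed=streams[3],
        )
        reads_out = synthesize_reads(
            out, ref, tag=tag, error_rate=error_rate,
            depth_per_mutant=depth_per_mutant, seed=streams[4],
        )
        return run_screen(reads_in, reads_out, ref, ann, tag=tag, threshold=threshold)
    return call_candidates(
        compute_insertion_index(sites_from_library(lib), ann),
        compute_insertion_index(sites_from_library(out), ann),
        threshold=threshold,
    )
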