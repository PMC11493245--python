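"""Surface-exclusion matrices and exclusion-group inference.

Donor strains whose conjugative plasmid carries a given *traN* adhesin
variant are mated against recipients expressing different *sfx* variants
(and against an empty reference recipient). Each (sfx, traN) cell of the
exclusion matrix is the exclusion index EI = T(empty) / T(sfx recipient)
for that donor. TraN variants whose exclusion profile — which sfx variants
exclude them — is identical form one surface-exclusion group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matingstats import transfer_frequencies

__all__ = [
    "ExclusionMatrix",
    "GroupPartition",
    "build_matrix",
    "infer_groups",
    "plot_heatmap",
]


@dataclass
class ExclusionMatrix:
    """Exclusion indices over sfx (rows) × traN (columns) variant pairs."""

    values: pd.DataFrame       # EI values, index = sfx labels, columns = traN labels
    lower_bound: pd.DataFrame  # same shape; True where the test frequency was censored

    def __post_init__(self):
        if not self.values.index.equals(self.lower_bound.index) or not self.values.columns.equals(
            self.lower_bound.columns
        ):
            raise ValueError("values and lower_bound must share labels")


@dataclass
class GroupPartition:
    """Surface-exclusion groups of traN variants.

    ``groups`` partitions the traN labels; ``sfx_assignment`` maps each sfx
    variant to the indices (into ``groups``) of the groups it excludes.
    """

    groups: list[frozenset]
    sfx_assignment: dict

    def group_of(self, tran_label: str) -> int:
        for i, g in enumerate(self.groups):
            if tran_label in g:
                return i
        raise KeyError(tran_label)


def _geomean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def build_matrix(
    matings: pd.DataFrame,
    reference_recipient: str = "empty",
    ei_mode: str = "geometric_mean",
) -> ExclusionMatrix:
    """Assemble the sfx × traN exclusion-index matrix from a CFU table.

    ``matings`` needs the mating CSV columns plus ``sfx_variant`` and
    ``traN_variant``; rows whose ``sfx_variant`` equals
    ``reference_recipient`` are the empty-recipient baselines. With
    ``ei_mode="geometric_mean"`` (default) each cell is the ratio of the
    geometric-mean baseline frequency to the geometric-mean test frequency
    for that donor; ``ei_mode="per_replicate"`` pairs replicates and takes
    the geometric mean of per-replicate ratios. A missing baseline for any
    traN column is an error; no partial matrix is returned.
    """
    if ei_mode not in ("geometric_mean", "per_replicate"):
        raise ValueError("ei_mode must be 'geometric_mean' or 'per_replicate'")
    for col in ("sfx_variant", "traN_variant"):
        if col not in matings.columns:
            raise ValueError(f"mating table missing column {col!r}")

    df = transfer_frequencies(matings)
    tran_labels = sorted(df["traN_variant"].unique())
    sfx_labels = sorted(set(df["sfx_variant"].unique()) - {reference_recipient})
    if not sfx_labels:
        raise ValueError("no test recipients found (only the reference recipient)")

    values = pd.DataFrame(np.nan, index=sfx_labels, columns=tran_labels, dtype=float)
    lower = pd.DataFrame(False, index=sfx_labels, columns=tran_labels)

    for t in tran_labels:
        base = df[(df["traN_variant"] == t) & (df["sfx_variant"] == reference_recipient)]
        if not len(base):
            raise ValueError(f"no empty-recipient baseline mating for traN column {t!r}")
        for s in sfx_labels:
            test = df[(df["traN_variant"] == t) & (df["sfx_variant"] == s)]
            if not len(test):
                continue  # cell explicitly missing
            if ei_mode == "geometric_mean":
                ei = _geomean(base["frequency"].to_numpy()) / _geomean(
                    test["frequency"].to_numpy()
                )
            else:
                merged = base.merge(test, on="replicate", suffixes=("_empty", "_test"))
                if not len(merged):
                    raise ValueError(
                        f"no paired replicates for cell ({s!r}, {t!r}) in per-replicate mode"
                    )
                ei = _geomean(
                    merged["frequency_empty"].to_numpy() / merged["frequency_test"].to_numpy()
                )
            values.loc[s, t] = ei
            lower.loc[s, t] = bool(test["censored"].any())
    return ExclusionMatrix(values=values, lower_bound=lower)


def infer_groups(matrix: ExclusionMatrix, exclusion_threshold: float = 10.0) -> GroupPartition:
    """Partition traN variants by their binarized exclusion profiles.

    Cells are binarized at ``exclusion_threshold`` (excluded iff
    EI >= threshold; censored lower-bound cells count as excluded when the
    bound clears the cutoff, which the plain comparison already implements).
    Missing cells are treated as EI = 1 (no exclusion) with a warning. TraN
    columns with identical binary profiles across all sfx rows share a
    group; groups are ordered by their alphabetically first member, so the
    partition does not depend on input row/column order.
    """
    values = matrix.values.copy()
    if values.isna().any().any():
        warnings.warn("missing exclusion-matrix cells treated as EI = 1", stacklevel=2)
        values = values.fillna(1.0)
    sfx_order = sorted(values.index)
    binary = values.loc[sfx_order] >= exclusion_threshold

    profiles: dict[tuple, list] = {}
    for t in sorted(values.columns):
        profiles.setdefault(tuple(binary[t].to_numpy()), []).append(t)
    groups = sorted((frozenset(m) for m in profiles.values()), key=lambda g: min(g))

    sfx_assignment = {}
    for s in sfx_order:
        excluded = {
            gi
            for gi, g in enumerate(groups)
            if any(bool(binary.loc[s, t]) for t in g)
        }
        sfx_assignment[s] = excluded
    return GroupPartition(groups=groups, sfx_assignment=sfx_assignment)


def plot_heatmap(matrix: ExclusionMatrix, path) -> None:
    """Write a log10-EI heatmap of the exclusion matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = np.log10(matrix.values.to_numpy(dtype=float))
    fig, ax = plt.subplots(figsize=(1.2 * matrix.values.shape[1] + 2, 1.0 * matrix.values.shape[0] + 2))
    im = ax.imshow(vals, cmap="viridis")
    ax.set_xticks(range(matrix.values.shape[1]), matrix.values.columns, rotation=45, ha="right")
    ax.set_yticks(range(matrix.values.shape[0]), matrix.values.index)
    ax.set_xlabel("traN variant (donor)")
    ax.set_ylabel("sfx variant (recipient)")
    fig.colorbar(im, ax=ax, label="log10 exclusion index")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
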