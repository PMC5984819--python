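"""Group-unique homozygous variant identification.

The expected signature of a de-novo mutation arising from transformation or
tissue culture is a homozygous alternate call shared by the replicated
plants of exactly one study group, while every other group (including the
untransformed controls) is homozygous reference.  This module implements
that rule with the study's missingness and within-group consensus
requirements:

* a variant is removed for a group when more than ``max_missing_frac`` of
  the group's calls are missing (default 1/3: 4 or more of 9 missing);
* a group reaches consensus when at least ``min_consensus`` samples share
  the same homozygous call (default 6 of 9); heterozygous calls never form
  a consensus;
* a variant is unique to group G iff G's consensus is HOM_ALT and every
  other group's consensus is HOM_REF.  A group with no consensus, or with
  too much missing data, disqualifies the variant entirely.

Missingness is evaluated before the consensus test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from varprov.model import GenotypeCall, GenotypeMatrix, StudyDesign, key_str


class Consensus(Enum):
    """Outcome of the within-group consensus test at one variant."""

    HOM_REF = "HOM_REF"
    HOM_ALT = "HOM_ALT"
    NO_CONSENSUS = "NO_CONSENSUS"
    MISSING_REMOVED = "MISSING_REMOVED"


@dataclass(frozen=True)
class UniquenessConfig:
    max_missing_frac: float = 1.0 / 3.0
    min_consensus: int = 6
    group_size: int = 9

    def __post_init__(self) -> None:
        if not (0 <= self.max_missing_frac < 1):
            raise ValueError("max_missing_frac must be in [0, 1)")
        if not (1 <= self.min_consensus <= self.group_size):
            raise ValueError("min_consensus must be in [1, group_size]")


def group_consensus(
    calls: Sequence[int | GenotypeCall], config: UniquenessConfig = UniquenessConfig()
) -> Consensus:
    """Consensus call for one group at one variant.

    Strictly more than ``max_missing_frac`` missing removes the variant
    (e.g. 3 of 9 = 33.3% survives a 1/3 threshold; 4 of 9 does not).
    """
    if len(calls) != config.group_size:
        raise ValueError(f"expected {config.group_size} calls, got {len(calls)}")
    codes = np.asarray([int(c) for c in calls], dtype=np.int8)
    n_missing = int(np.sum(codes == GenotypeCall.MISSING))
    if n_missing / config.group_size > config.max_missing_frac:
        return Consensus.MISSING_REMOVED
    if int(np.sum(codes == GenotypeCall.HOM_ALT)) >= config.min_consensus:
        return Consensus.HOM_ALT
    if int(np.sum(codes == GenotypeCall.HOM_REF)) >= config.min_consensus:
        return Consensus.HOM_REF
    return Consensus.NO_CONSENSUS


@dataclass
class GroupUniqueSets:
    """Per-group sets of variant keys unique to that group, with provenance.

    ``provenance`` records, for each unique variant, the owning group and
    its homozygous-alternate support count.  The sets are pairwise disjoint
    by construction (one group must be HOM_ALT and all others HOM_REF).
    """

    sets: dict[str, set[tuple[str, int, str, str]]]
    provenance: dict[tuple[str, int, str, str], dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str, str]] = set()
        for group, keys in self.sets.items():
            overlap = seen & keys
            if overlap:
                raise ValueError(f"variant(s) {sorted(overlap)[:3]} appear in multiple group sets")
            seen |= keys

    def total(self) -> int:
        return sum(len(s) for s in self.sets.values())


def _consensus_codes(
    calls: np.ndarray, cols: np.ndarray, config: UniquenessConfig
) -> np.ndarray:
    """Vectorised consensus over all variants for one group's columns.

    Returns an int8 vector: 0=HOM_REF, 2=HOM_ALT, -2=NO_CONSENSUS,
    -3=MISSING_REMOVED.
    """
    sub = calls[:, cols]
    size = len(cols)
    n_missing = np.sum(sub == GenotypeCall.MISSING, axis=1)
    n_alt = np.sum(sub == GenotypeCall.HOM_ALT, axis=1)
    n_ref = np.sum(sub == GenotypeCall.HOM_REF, axis=1)
    out = np.full(calls.shape[0], -2, dtype=np.int8)
    out[n_ref >= config.min_consensus] = 0
    out[n_alt >= config.min_consensus] = 2
    out[n_missing / size > config.max_missing_frac] = -3
    return out


_CODE_TO_CONSENSUS = {
    0: Consensus.HOM_REF,
    2: Consensus.HOM_ALT,
    -2: Consensus.NO_CONSENSUS,
    -3: Consensus.MISSING_REMOVED,
}


def unique_homozygous_sets(
    matrix: GenotypeMatrix,
    design: StudyDesign,
    config: UniquenessConfig = UniquenessConfig(),
) -> GroupUniqueSets:
    """Identify variants uniquely homozygous-alternate in one group.

    The matrix must already be restricted to PASS records (apply the hard
    filters first).  Group sizes are taken from the design; each must equal
    ``config.group_size``.
    """
    if matrix.samples != design.samples:
        raise ValueError("matrix samples do not match design samples")
    group_cols: dict[str, np.ndarray] = {}
    for g in design.groups:
        cols = matrix.sample_index(design.samples_in_group(g))
        if len(cols) != config.group_size:
            raise ValueError(
                f"group {g!r} has {len(cols)} samples; config.group_size={config.group_size}"
            )
        group_cols[g] = cols

    cons = np.stack(
        [_consensus_codes(matrix.calls, group_cols[g], config) for g in design.groups]
    )  # (G, V)
    n_alt_groups = np.sum(cons == 2, axis=0)
    n_ref_groups = np.sum(cons == 0, axis=0)
    n_groups = len(design.groups)
    # unique iff exactly one HOM_ALT consensus and HOM_REF consensus everywhere else
    unique_mask = (n_alt_groups == 1) & (n_ref_groups == n_groups - 1)

    sets: dict[str, set] = {g: set() for g in design.groups}
    provenance: dict = {}
    for v in np.flatnonzero(unique_mask):
        gi = int(np.argmax(cons[:, v] == 2))
        g = design.groups[gi]
        key = matrix.variants[v]
        sets[g].add(key)
        sub = matrix.calls[v, group_cols[g]]
        provenance[key] = {
            "group": g,
            "n_hom_alt": int(np.sum(sub == GenotypeCall.HOM_ALT)),
            "n_missing": int(np.sum(sub == GenotypeCall.MISSING)),
            "consensus": {
                h: _CODE_TO_CONSENSUS[int(cons[hi, v])].value
                for hi, h in enumerate(design.groups)
            },
        }
    return GroupUniqueSets(sets=sets, provenance=provenance)


def count_table(sets: GroupUniqueSets) -> pd.Series:
    """Per-group counts of unique variants (sums to the overall total)."""
    return pd.Series({g: len(s) for g, s in sets.sets.items()}, name="unique_variants")


def unique_sets_table(sets: GroupUniqueSets, path: str | Path | None = None) -> pd.DataFrame:
    """Long-form table of unique variants (variant key, group, support)."""
    rows = []
    for g in sets.sets:
        for key in sorted(sets.sets[g]):
            prov = sets.provenance.get(key, {})
            rows.append(
                {
                    "variant": key_str(key),
                    "group": g,
                    "n_hom_alt": prov.get("n_hom_alt"),
                    "n_missing": prov.get("n_missing"),
                }
            )
    df = pd.DataFrame(rows, columns=["variant", "group", "n_hom_alt", "n_missing"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
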