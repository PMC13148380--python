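"""Signed-sum transcriptional activity scores for gene signatures.

A signature is a pair of up/down gene sets (e.g. genes induced or
repressed when a pathway such as BAP1 is active). The per-sample score on
a log2 expression matrix is the sum of expression over up-genes minus the
sum over down-genes; lower scores indicate less activity. Includes
ortholog mapping of signatures between species (with exclusion
bookkeeping) and a sensitivity check correlating scores from a full vs a
reduced signature.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _sstats

__all__ = [
    "SignatureGeneSet",
    "CoverageReport",
    "OrthologReport",
    "activity_score",
    "map_orthologs",
    "sensitivity_check",
    "read_signature",
    "read_ortholog_map",
]


@dataclasses.dataclass(frozen=True)
class SignatureGeneSet:
    """Up/down gene identifier sets defining an activity signature."""

    up: frozenset
    down: frozenset
    species: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        if not self.up or not self.down:
            raise ValueError("both up and down gene sets must be nonempty")
        overlap = self.up & self.down
        if overlap:
            raise ValueError(f"up and down sets overlap: {sorted(overlap)[:5]}")


@dataclasses.dataclass
class CoverageReport:
    """Which signature genes the expression matrix actually covered."""

    n_up: int
    n_down: int
    n_up_present: int
    n_down_present: int
    missing_up: list
    missing_down: list

    @property
    def coverage(self) -> float:
        return (self.n_up_present + self.n_down_present) / (self.n_up + self.n_down)


@dataclasses.dataclass
class OrthologReport:
    excluded_up: list
    excluded_down: list
    removed_ambiguous: list
    n_input: int

    @property
    def exclusion_fraction(self) -> float:
        return (len(self.excluded_up) + len(self.excluded_down)) / self.n_input


def activity_score(
    expr: pd.DataFrame, sig: SignatureGeneSet
) -> tuple[pd.Series, CoverageReport]:
    """Per-sample signed-sum activity score.

    ``score(s) = sum_{g in up} expr[g, s] - sum_{g in down} expr[g, s]``
    over the signature genes present in the matrix (rows = genes,
    columns = samples). Missing genes are skipped and reported, never
    imputed.
    """
    idx = pd.Index(expr.index)
    up_present = sorted(sig.up & set(idx))
    down_present = sorted(sig.down & set(idx))
    if not up_present and not down_present:
        raise ValueError(
            "signature has zero overlap with the expression matrix; "
            f"matrix genes look like {idx[:5].tolist()}, "
            f"signature genes like {sorted(sig.up)[:5]}"
        )
    score = expr.loc[up_present].sum(axis=0) - expr.loc[down_present].sum(axis=0)
    score.name = "activity_score"
    report = CoverageReport(
        n_up=len(sig.up),
        n_down=len(sig.down),
        n_up_present=len(up_present),
        n_down_present=len(down_present),
        missing_up=sorted(sig.up - set(up_present)),
        missing_down=sorted(sig.down - set(down_present)),
    )
    return score, report


def map_orthologs(
    sig: SignatureGeneSet, mapping: dict
) -> tuple[SignatureGeneSet, OrthologReport]:
    """Translate a signature through an ortholog map (many-to-one allowed).

    Genes without an ortholog are excluded and reported with the overall
    exclusion fraction. Duplicate targets collapse to one gene; a target
    reached from both the up and the down set is removed from both and
    reported as ambiguous.
    """
    excluded_up = sorted(g for g in sig.up if g not in mapping)
    excluded_down = sorted(g for g in sig.down if g not in mapping)
    up = {mapping[g] for g in sig.up if g in mapping}
    down = {mapping[g] for g in sig.down if g in mapping}
    ambiguous = up & down
    up -= ambiguous
    down -= ambiguous
    report = OrthologReport(
        excluded_up=excluded_up,
        excluded_down=excluded_down,
        removed_ambiguous=sorted(ambiguous),
        n_input=len(sig.up) + len(sig.down),
    )
    new_sig = SignatureGeneSet(
        up=frozenset(up),
        down=frozenset(down),
        species=sig.species,
        provenance=sig.provenance + " (ortholog-mapped)",
    )
    return new_sig, report


def sensitivity_check(
    expr: pd.DataFrame, full: SignatureGeneSet, reduced: SignatureGeneSet
) -> float:
    """Pearson correlation of per-sample scores under full vs reduced
    signatures; NaN (with a warning) if either score vector is constant."""
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples for a meaningful correlation")
    s_full, _ = activity_score(expr, full)
    s_red, _ = activity_score(expr, reduced)
    if np.std(s_full) == 0 or np.std(s_red) == 0:
        warnings.warn("zero-variance score vector; correlation undefined")
        return float("nan")
    return float(_sstats.pearsonr(s_full, s_red).statistic)


def read_signature(path: str | Path, species: str = "") -> SignatureGeneSet:
    """Read a two-column TSV (gene, direction in {up, down})."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "direction"], comment="#")
    directions = set(df["direction"])
    if not directions <= {"up", "down"}:
        raise ValueError(f"unexpected directions {directions - {'up', 'down'}}")
    return SignatureGeneSet(
        up=frozenset(df.loc[df["direction"] == "up", "gene"]),
        down=frozenset(df.loc[df["direction"] == "down", "gene"]),
        species=species,
        provenance=str(path),
    )


def read_ortholog_map(path: str | Path) -> dict:
    """Read a two-column TSV (source gene, target gene) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["source", "target"], comment="#")
    return dict(zip(df["source"], df["target"]))
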