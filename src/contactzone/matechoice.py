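"""Paternity assignment by genotypic exclusion and assortative-mating tests.

Each brood is a mouthbrooding female plus a sample of her fry, genotyped at
a shared set of microsatellite loci.  A candidate sire is compatible with a
fry at a locus if, after removing one fry allele matching the mother, the
remaining allele occurs in the candidate's genotype.  Candidates failing at
more loci than the mismatch tolerance (default 0, strict exclusion) are
excluded; a brood with exactly one surviving candidate is an assigned
mating.  Because some mouthbrooders show multiple paternity, a brood with
no single compatible sire is split greedily into at most two sire blocks.

Assortment is tested per experimental replicate with a one-sided exact
binomial test on the count of heterotypic (between-lineage) matings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class Brood:
    """One mouthbrooding female's genotype, her sampled fry, and the replicate."""

    brood_id: str
    mother_id: str
    mother: np.ndarray  # (n_loci, 2)
    fry: np.ndarray  # (n_fry, n_loci, 2)
    replicate_id: str = "1"

    def __post_init__(self) -> None:
        self.mother = np.asarray(self.mother, dtype=int)
        self.fry = np.asarray(self.fry, dtype=int)
        if self.mother.ndim != 2 or self.mother.shape[1] != 2:
            raise ValueError("mother genotype must be (n_loci, 2)")
        if self.mother.size == 0:
            raise ValueError(f"brood {self.brood_id!r}: missing mother genotype")
        if self.fry.ndim != 3 or self.fry.shape[1:] != self.mother.shape:
            raise ValueError("fry genotypes must be (n_fry, n_loci, 2) over the mother's loci")
        if self.fry.shape[0] < 1:
            raise ValueError(f"brood {self.brood_id!r}: no fry")


@dataclass
class MatingRecord:
    """The resolved outcome of one mating within a brood."""

    brood_id: str
    status: str  # "assigned" | "ambiguous" | "excluded"
    assigned_father_id: str | None = None
    female_lineage: str | None = None
    male_lineage: str | None = None
    multiple_paternity: bool = False
    replicate_id: str = "1"

    @property
    def homotypic(self) -> bool:
        if self.status != "assigned":
            raise ValueError("homotypic is defined only for assigned matings")
        return self.female_lineage == self.male_lineage


@dataclass
class BinomialTestResult:
    k: int
    n: int
    p0: float
    p_value: float
    alternative: str = "less"


def _locus_compatible(fry_locus: np.ndarray, mother_locus: np.ndarray, cand_locus: np.ndarray) -> bool:
    """Can the fry genotype arise from this mother-candidate pair at one locus?

    Missing alleles (0) on any side make the locus uninformative.
    """
    if 0 in fry_locus or 0 in mother_locus or 0 in cand_locus:
        return True
    f1, f2 = int(fry_locus[0]), int(fry_locus[1])
    m = set(int(a) for a in mother_locus)
    c = set(int(a) for a in cand_locus)
    return (f1 in m and f2 in c) or (f2 in m and f1 in c)


def _failed_loci(brood: Brood, candidate: np.ndarray, fry_index: Iterable[int] | None = None) -> set[int]:
    """Loci at which any of the given fry is inexplicable for this candidate."""
    fry_index = range(brood.fry.shape[0]) if fry_index is None else fry_index
    failed = set()
    for locus in range(brood.mother.shape[0]):
        for i in fry_index:
            if not _locus_compatible(brood.fry[i, locus], brood.mother[locus], candidate[locus]):
                failed.add(locus)
                break
    return failed


def assign_paternity(
    brood: Brood,
    candidates: Mapping[str, np.ndarray],
    lineages: Mapping[str, str] | None = None,
    mother_lineage: str | None = None,
    mismatch_tolerance: int = 0,
    allow_multiple_paternity: bool = True,
) -> list[MatingRecord]:
    """Assign the brood's sire(s) by exclusion among candidate fathers.

    A candidate survives if the number of loci at which any fry is
    inexplicable is at most ``mismatch_tolerance``.  One survivor gives an
    assigned mating; several give an ambiguous record; none, when multiple
    paternity is allowed, triggers a greedy split of the fry into at most
    two sire blocks, each counted as a mating flagged ``multiple_paternity``.
    Returns a list of records (length 1 except under multiple paternity).
    """
    if not candidates:
        raise ValueError("at least one candidate father required")
    cand = {cid: np.asarray(g, dtype=int) for cid, g in candidates.items()}
    n_loci = brood.mother.shape[0]
    for cid, g in cand.items():
        if g.shape != (n_loci, 2):
            raise ValueError(f"candidate {cid!r} genotyped at a different locus set")
    lineages = lineages or {}

    def record(status, father=None, multiple=False):
        return MatingRecord(
            brood_id=brood.brood_id,
            status=status,
            assigned_father_id=father,
            female_lineage=mother_lineage,
            male_lineage=lineages.get(father) if father else None,
            multiple_paternity=multiple,
            replicate_id=brood.replicate_id,
        )

    survivors = [cid for cid in cand if len(_failed_loci(brood, cand[cid])) <= mismatch_tolerance]
    if len(survivors) == 1:
        return [record("assigned", survivors[0])]
    if len(survivors) > 1:
        return [record("ambiguous")]
    if not allow_multiple_paternity:
        return [record("excluded")]

    # greedy two-sire split: give the largest explicable fry block to the best
    # candidate, then require a single candidate to explain the remainder
    n_fry = brood.fry.shape[0]
    per_cand_ok: dict[str, set[int]] = {}
    for cid, g in cand.items():
        ok = {
            i
            for i in range(n_fry)
            if len(_failed_loci(brood, g, fry_index=[i])) <= mismatch_tolerance
        }
        per_cand_ok[cid] = ok
    first = max(sorted(per_cand_ok), key=lambda c: len(per_cand_ok[c]))
    block1 = per_cand_ok[first]
    if not block1:
        return [record("excluded")]
    remainder = set(range(n_fry)) - block1
    if not remainder:
        # full block explicable fry-by-fry but candidate failed jointly cannot
        # happen with per-fry union logic; treat as single assigned sire
        return [record("assigned", first, multiple=False)]
    second_candidates = [
        cid for cid in sorted(cand) if cid != first and remainder <= per_cand_ok[cid]
    ]
    if len(second_candidates) == 1:
        return [
            record("assigned", first, multiple=True),
            record("assigned", second_candidates[0], multiple=True),
        ]
    if len(second_candidates) > 1:
        return [record("assigned", first, multiple=True), record("ambiguous", multiple=True)]
    return [record("excluded")]


def tally_matings(records: Iterable[MatingRecord]) -> pd.DataFrame:
    """Per-replicate (and pooled) counts of heterotypic vs assigned matings.

    Ambiguous and excluded records do not enter ``n``.
    """
    per: dict[str, list[int]] = {}
    for rec in records:
        if rec.status != "assigned":
            continue
        k_n = per.setdefault(rec.replicate_id, [0, 0])
        k_n[1] += 1
        if not rec.homotypic:
            k_n[0] += 1
    rows = [
        {"replicate": rep, "k_heterotypic": kn[0], "n_assigned": kn[1],
         "heterotypic_pct": 100.0 * kn[0] / kn[1] if kn[1] else float("nan")}
        for rep, kn in sorted(per.items())
    ]
    total_k = sum(r["k_heterotypic"] for r in rows)
    total_n = sum(r["n_assigned"] for r in rows)
    rows.append(
        {"replicate": "pooled", "k_heterotypic": total_k, "n_assigned": total_n,
         "heterotypic_pct": 100.0 * total_k / total_n if total_n else float("nan")}
    )
    return pd.DataFrame(rows)


def binomial_assortment_test(
    k: int, n: int, p0: float = 0.5, alternative: str = "less"
) -> BinomialTestResult:
    """Exact binomial test of the heterotypic mating count.

    The default one-sided lower tail P(X <= k | n, p0) tests a directional
    preference for homotypic mates; the tail is summed exactly over the
    binomial mass (rational arithmetic, then converted to float).
    ``alternative="two-sided"`` sums all outcomes with mass not exceeding
    the observed one.
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie strictly between 0 and 1")
    p = Fraction(p0).limit_denominator(10**9)
    q = 1 - p

    def mass(i: int) -> Fraction:
        return comb(n, i) * p**i * q ** (n - i)

    if alternative == "less":
        tail = sum(mass(i) for i in range(k + 1))
    elif alternative == "greater":
        tail = sum(mass(i) for i in range(k, n + 1))
    elif alternative == "two-sided":
        mk = mass(k)
        tail = sum(m for m in (mass(i) for i in range(n + 1)) if m <= mk)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return BinomialTestResult(k=k, n=n, p0=p0, p_value=float(min(tail, Fraction(1))), alternative=alternative)


def replicate_tests(
    records: Iterable[MatingRecord], p0: float = 0.5, alternative: str = "less"
) -> pd.DataFrame:
    """Assortment test per replicate, from resolved mating records."""
    tally = tally_matings(records)
    out = []
    for _, row in tally.iterrows():
        if row["n_assigned"] == 0:
            pv = float("nan")
        else:
            pv = binomial_assortment_test(
                int(row["k_heterotypic"]), int(row["n_assigned"]), p0, alternative
            ).p_value
        out.append({**row.to_dict(), "p_value": pv})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# genotype-table I/O for broods and candidates


def read_brood_tables(
    broods_path, candidates_path
) -> tuple[list[Brood], dict[str, np.ndarray], dict[str, str], dict[str, str]]:
    """Read broods and candidate fathers from delimited genotype tables.

    The brood table has columns ``brood_id``, ``replicate``, ``role``
    (``mother``/``fry``), ``individual``, ``lineage`` (mothers only) and two
    columns per locus (``<locus>.1``, ``<locus>.2``).  The candidate table
    has ``individual``, ``lineage`` and the same locus columns.

    Returns broods, candidate genotypes, candidate lineages and mother
    lineages keyed by brood id.
    """
    bdf = pd.read_csv(broods_path, sep=None, engine="python")
    cdf = pd.read_csv(candidates_path, sep=None, engine="python")
    locus_cols = [c for c in bdf.columns if "." in c]
    loci = list(dict.fromkeys(c.rsplit(".", 1)[0] for c in locus_cols))

    def geno(row) -> np.ndarray:
        return np.array([[int(row[f"{l}.1"]), int(row[f"{l}.2"])] for l in loci])

    broods = []
    mother_lineage: dict[str, str] = {}
    for bid, grp in bdf.groupby("brood_id", sort=True):
        mothers = grp[grp["role"] == "mother"]
        if len(mothers) != 1:
            raise ValueError(f"brood {bid!r}: expected exactly one mother row")
        mrow = mothers.iloc[0]
        fry = np.stack([geno(r) for _, r in grp[grp["role"] == "fry"].iterrows()])
        broods.append(
            Brood(
                brood_id=str(bid),
                mother_id=str(mrow["individual"]),
                mother=geno(mrow),
                fry=fry,
                replicate_id=str(mrow["replicate"]),
            )
        )
        mother_lineage[str(bid)] = str(mrow["lineage"])

    candidates = {str(r["individual"]): geno(r) for _, r in cdf.iterrows()}
    cand_lineage = {str(r["individual"]): str(r["lineage"]) for _, r in cdf.iterrows()}
    return broods, candidates, cand_lineage, mother_lineage
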