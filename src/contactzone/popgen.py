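"""Contact-zone population genetics.

Covers the mtDNA side (alignment site filtering, haplotype collapsing,
minimum-spanning haplotype networks, in-silico diagnostic restriction
screening) and the nuclear side (pairwise Weir-Cockerham FST from diploid
microsatellite genotypes, with permutation p-values).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGT")
# anything outside A/C/G/T is treated as unresolved: gaps, N and IUPAC ambiguity codes
AMBIGUOUS = frozenset("-NRYSWKMBDHV.?")

# HpaI recognition site; palindromic, so the forward strand suffices
HPAI_MOTIF = "GTTAAC"


class AmbiguousSequenceError(ValueError):
    """Raised when an analysis cannot proceed because of unresolved bases."""


@dataclass
class SequenceAlignment:
    """A multiple alignment of equal-length nucleotide sequences."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths in alignment: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.records.values())))

    @property
    def n_records(self) -> int:
        return len(self.records)

    def to_matrix(self) -> np.ndarray:
        """(n_records, length) uppercase character matrix."""
        return np.array([list(s.upper()) for s in self.records.values()])


@dataclass
class HaplotypeSet:
    """Distinct sequences with their frequencies and record membership."""

    haplotypes: dict[str, str]
    counts: dict[str, int]
    membership: dict[str, str]  # record id -> haplotype id

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def ids(self) -> list[str]:
        return list(self.haplotypes)


@dataclass
class HaploNetwork:
    """Minimum-spanning haplotype network.

    ``edges`` form a minimum spanning tree over haplotypes (mutational
    steps as weights); ``alternative_edges`` are equal-length connections
    not in the tree — pairs whose direct distance equals the largest step
    on the tree path between them, which a network display shows as
    alternative links.
    """

    nodes: list[tuple[str, int]]  # (haplotype id, frequency)
    edges: list[tuple[str, str, int]]
    alternative_edges: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges)


@dataclass
class GenotypeMatrix:
    """Diploid genotypes: (individuals, loci, 2) integer alleles, 0 = missing."""

    genotypes: np.ndarray
    individuals: list[str]
    loci: list[str]
    pop: dict[str, str]  # individual -> population label

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=int)
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError("genotypes must be (n_individuals, n_loci, 2)")
        if self.genotypes.shape[0] != len(self.individuals):
            raise ValueError("genotype rows must match individual names")
        if self.genotypes.shape[1] != len(self.loci):
            raise ValueError("genotype columns must match locus names")
        if np.any(self.genotypes < 0):
            raise ValueError("allele labels must be positive integers (0 = missing)")
        missing_pop = [i for i in self.individuals if i not in self.pop]
        if missing_pop:
            raise ValueError(f"individuals without a population label: {missing_pop[:10]}")

    def populations(self) -> list[str]:
        return sorted(set(self.pop.values()))

    def subset(self, pops: list[str]) -> "GenotypeMatrix":
        keep = [i for i, ind in enumerate(self.individuals) if self.pop[ind] in pops]
        inds = [self.individuals[i] for i in keep]
        return GenotypeMatrix(self.genotypes[keep], inds, self.loci, {i: self.pop[i] for i in inds})


@dataclass
class FstResult:
    pair: tuple[str, str]
    theta: float
    p_value: float
    n_perm: int


# ---------------------------------------------------------------------------
# mtDNA: filtering, haplotypes, network, RFLP


def read_fasta_alignment(path: str | Path) -> SequenceAlignment:
    """Read an aligned FASTA file (all sequences equal length)."""
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return SequenceAlignment(records)


def write_fasta_alignment(aln: SequenceAlignment, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for rid, seq in aln.records.items():
            fh.write(f">{rid}\n{seq}\n")
    return path


def filter_alignment_sites(aln: SequenceAlignment) -> SequenceAlignment:
    """Remove every alignment column containing a gap or unresolved base.

    A column is dropped if any record carries '-', 'N' or an IUPAC
    ambiguity code there (case-insensitive).  Idempotent.
    """
    mat = aln.to_matrix()
    clean = np.all(np.isin(mat, list(VALID_BASES)), axis=0)
    if not clean.any():
        raise ValueError("no alignment columns survive gap/ambiguity filtering")
    kept = mat[:, clean]
    return SequenceAlignment({rid: "".join(row) for rid, row in zip(aln.records, kept)})


def collapse_haplotypes(aln: SequenceAlignment) -> HaplotypeSet:
    """Merge identical sequences (case-insensitive) into haplotypes.

    Requires a site-filtered alignment; haplotype ids are assigned in order
    of first appearance (H1, H2, ...).
    """
    first = next(iter(aln.records.values())).upper()
    if any(c not in VALID_BASES for c in first) or any(
        c not in VALID_BASES for s in aln.records.values() for c in s.upper()
    ):
        raise AmbiguousSequenceError(
            "alignment still contains gaps or unresolved bases; run filter_alignment_sites first"
        )
    haplotypes: dict[str, str] = {}
    counts: dict[str, int] = {}
    membership: dict[str, str] = {}
    seq_to_id: dict[str, str] = {}
    for rid, seq in aln.records.items():
        s = seq.upper()
        hid = seq_to_id.get(s)
        if hid is None:
            hid = f"H{len(seq_to_id) + 1}"
            seq_to_id[s] = hid
            haplotypes[hid] = s
            counts[hid] = 0
        counts[hid] += 1
        membership[rid] = hid
    return HaplotypeSet(haplotypes=haplotypes, counts=counts, membership=membership)


def pairwise_differences(haps: HaplotypeSet) -> pd.DataFrame:
    """Hamming distance matrix between haplotypes (mutational steps)."""
    ids = haps.ids()
    seqs = [haps.haplotypes[h] for h in ids]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError("haplotypes differ in length; cannot compute site differences")
    mat = np.array([list(s) for s in seqs])
    d = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
    return pd.DataFrame(d, index=ids, columns=ids)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_msn(dist: pd.DataFrame | np.ndarray, counts: dict[str, int] | None = None) -> HaploNetwork:
    """Minimum-spanning network over haplotypes from a distance matrix.

    Kruskal's algorithm with deterministic tie-breaking by the sorted node-id
    pair gives the tree; every non-tree pair whose direct distance equals the
    bottleneck (maximum step) on its tree path is reported as an alternative
    equal-length connection.
    """
    if isinstance(dist, pd.DataFrame):
        ids = list(dist.index)
        d = dist.to_numpy()
    else:
        d = np.asarray(dist)
        ids = [f"H{i + 1}" for i in range(d.shape[0])]
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if not np.array_equal(d, d.T):
        raise ValueError("distance matrix must be symmetric")

    counts = counts or {h: 1 for h in ids}
    nodes = [(h, int(counts.get(h, 1))) for h in ids]
    m = len(ids)
    if m == 1:
        return HaploNetwork(nodes=nodes, edges=[], alternative_edges=[])

    pairs = sorted(
        ((int(d[i, j]),) + tuple(sorted((ids[i], ids[j]))) for i, j in itertools.combinations(range(m), 2))
    )
    uf = _UnionFind(ids)
    tree: list[tuple[str, str, int]] = []
    for w, a, b in pairs:
        if uf.union(a, b):
            tree.append((a, b, w))
        if len(tree) == m - 1:
            break

    # bottleneck on tree paths via BFS per node (m is small for haplotype data)
    adj: dict[str, list[tuple[str, int]]] = {h: [] for h in ids}
    for a, b, w in tree:
        adj[a].append((b, w))
        adj[b].append((a, w))

    def bottlenecks_from(src: str) -> dict[str, int]:
        best = {src: 0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in best:
                    best[v] = max(best[u], w)
                    stack.append(v)
        return best

    tree_set = {(a, b) for a, b, _ in tree}
    alternatives = []
    for i in range(m):
        bn = bottlenecks_from(ids[i])
        for j in range(i + 1, m):
            a, b = sorted((ids[i], ids[j]))
            if (a, b) in tree_set:
                continue
            if int(d[i, j]) == bn[ids[j]]:
                alternatives.append((a, b, int(d[i, j])))
    alternatives.sort()
    return HaploNetwork(nodes=nodes, edges=tree, alternative_edges=alternatives)


def rflp_assign(seq: str, site: str = HPAI_MOTIF) -> str:
    """In-silico restriction screen: does the recognition motif occur?

    Returns ``"cut"`` when the motif is present on the forward strand
    (case-insensitive; HpaI's GTTAAC is its own reverse complement, so one
    strand suffices) and ``"uncut"`` otherwise.  An ``N`` inside any window
    that otherwise matches the motif makes the call indeterminate.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    motif = site.upper()
    bad = set(s) - (VALID_BASES | {"N"})
    if bad:
        raise ValueError(f"unexpected characters in sequence: {sorted(bad)}")
    L, w = len(s), len(motif)
    indeterminate = False
    for i in range(L - w + 1):
        window = s[i : i + w]
        if window == motif:
            return "cut"
        if "N" in window and all(a == b or a == "N" for a, b in zip(window, motif)):
            indeterminate = True
    if indeterminate:
        raise AmbiguousSequenceError("N overlaps a potential recognition site; call indeterminate")
    return "uncut"


# ---------------------------------------------------------------------------
# nuclear markers: Weir-Cockerham theta and permutation test


def _wc_components(genos_a: np.ndarray, genos_b: np.ndarray) -> tuple[float, float, float]:
    """Variance components (a, b, c) summed over alleles for one locus, two pops.

    Weir & Cockerham's (1984) estimator: ``a`` is the among-population
    component, ``b`` among individuals within populations, ``c`` within
    individuals; theta = a / (a + b + c).  Individuals with missing data at
    the locus are excluded.
    """
    r = 2
    samples = []
    for genos in (genos_a, genos_b):
        complete = genos[np.all(genos > 0, axis=1)]
        samples.append(complete)
    n_i = np.array([s.shape[0] for s in samples], dtype=float)
    if np.any(n_i < 2):
        return 0.0, 0.0, 0.0  # locus uninformative for this pair

    alleles = np.unique(np.concatenate([s.ravel() for s in samples]))
    n_bar = n_i.mean()
    n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)

    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p_i = np.array([(s == allele).mean() for s in samples])
        h_i = np.array([((s == allele).sum(axis=1) == 1).mean() for s in samples])
        p_bar = (n_i * p_i).sum() / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum() / (r * n_bar)

        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def wc_fst(g: GenotypeMatrix, popA: str, popB: str) -> float:
    """Pairwise Weir-Cockerham theta between two populations.

    Multiallelic; averaged over loci as the ratio of summed variance
    components.  Missing genotypes are excluded per locus; the estimate can
    be negative and is reported as computed.
    """
    idx_a = [i for i, ind in enumerate(g.individuals) if g.pop[ind] == popA]
    idx_b = [i for i, ind in enumerate(g.individuals) if g.pop[ind] == popB]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError(f"need >=2 individuals per population ({popA}: {len(idx_a)}, {popB}: {len(idx_b)})")
    return _theta_from_indices(g.genotypes, np.array(idx_a), np.array(idx_b))


def _theta_from_indices(genotypes: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    num = den = 0.0
    for locus in range(genotypes.shape[1]):
        a, b, c = _wc_components(genotypes[idx_a, locus], genotypes[idx_b, locus])
        num += a
        den += a + b + c
    if den == 0.0:
        raise ValueError("no polymorphic shared locus; theta undefined")
    return num / den


def fst_permutation_test(
    g: GenotypeMatrix, popA: str, popB: str, n_perm: int = 1000, seed: int | np.random.SeedSequence = 0
) -> FstResult:
    """Permutation test of differentiation between two populations.

    Individuals are shuffled between the two populations; the p-value is
    ``(1 + #{theta_perm >= theta_obs}) / (n_perm + 1)`` (add-one rule, so p
    is never below ``1/(n_perm+1)``).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    theta_obs = wc_fst(g, popA, popB)
    idx_a = np.array([i for i, ind in enumerate(g.individuals) if g.pop[ind] == popA])
    idx_b = np.array([i for i, ind in enumerate(g.individuals) if g.pop[ind] == popB])
    pooled = np.concatenate([idx_a, idx_b])
    na = idx_a.size
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        try:
            theta_p = _theta_from_indices(g.genotypes, perm[:na], perm[na:])
        except ValueError:
            theta_p = 0.0
        if theta_p >= theta_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return FstResult(pair=(popA, popB), theta=theta_obs, p_value=p, n_perm=n_perm)


def pairwise_fst_table(
    g: GenotypeMatrix, n_perm: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Theta and permutation p for every population pair."""
    rows = []
    pops = g.populations()
    for i, (pa, pb) in enumerate(itertools.combinations(pops, 2)):
        res = fst_permutation_test(g, pa, pb, n_perm=n_perm, seed=np.random.SeedSequence([seed, i]))
        rows.append({"popA": pa, "popB": pb, "theta": res.theta, "p_value": res.p_value, "n_perm": n_perm})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genotype file I/O


def read_genotype_table(path: str | Path) -> GenotypeMatrix:
    """Read a plain delimited genotype table.

    Expected columns: ``individual``, ``population``, then two columns per
    locus named ``<locus>.1`` and ``<locus>.2``.  Missing alleles are 0.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    lower = {c.lower(): c for c in df.columns}
    if "individual" not in lower or "population" not in lower:
        raise ValueError("genotype table needs 'individual' and 'population' columns")
    ind_col, pop_col = lower["individual"], lower["population"]
    allele_cols = [c for c in df.columns if c not in (ind_col, pop_col)]
    loci = list(dict.fromkeys(c.rsplit(".", 1)[0] for c in allele_cols))
    genos = np.zeros((len(df), len(loci), 2), dtype=int)
    for j, locus in enumerate(loci):
        for k in (1, 2):
            col = f"{locus}.{k}"
            if col not in df.columns:
                raise ValueError(f"missing allele column {col!r}")
            genos[:, j, k - 1] = df[col].fillna(0).astype(int)
    individuals = df[ind_col].astype(str).tolist()
    pop = dict(zip(individuals, df[pop_col].astype(str)))
    return GenotypeMatrix(genos, individuals, loci, pop)


def write_genotype_table(g: GenotypeMatrix, path: str | Path) -> Path:
    path = Path(path)
    cols: dict[str, object] = {
        "individual": g.individuals,
        "population": [g.pop[i] for i in g.individuals],
    }
    for j, locus in enumerate(g.loci):
        cols[f"{locus}.1"] = g.genotypes[:, j, 0]
        cols[f"{locus}.2"] = g.genotypes[:, j, 1]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    return path


def read_genepop(path: str | Path) -> GenotypeMatrix:
    """Read a Genepop-format genotype file (2- or 3-digit allele coding).

    The first line is a title; locus names follow (one per line, or one
    comma-separated line); ``POP`` lines delimit populations; individual
    lines are ``name , 001002 003004 ...``.  Populations are named after
    the last individual in each block, the Genepop convention.
    """
    lines = [ln.rstrip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 3:
        raise ValueError("not a Genepop file: too few lines")
    body = lines[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        chunk = [t.strip() for t in body[i].split(",") if t.strip()]
        loci.extend(chunk)
        i += 1
    if i == len(body):
        raise ValueError("not a Genepop file: no POP line found")

    blocks: list[list[tuple[str, list[str]]]] = []
    current: list[tuple[str, list[str]]] = []
    for ln in body[i:]:
        if ln.strip().upper() == "POP":
            if current:
                blocks.append(current)
            current = []
            continue
        if "," not in ln:
            raise ValueError(f"malformed Genepop individual line: {ln!r}")
        name, _, geno = ln.partition(",")
        current.append((name.strip(), geno.split()))
    if current:
        blocks.append(current)

    individuals: list[str] = []
    pop: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for block in blocks:
        pop_name = block[-1][0]
        for name, tokens in block:
            if len(tokens) != len(loci):
                raise ValueError(f"individual {name!r}: {len(tokens)} genotypes for {len(loci)} loci")
            row = np.zeros((len(loci), 2), dtype=int)
            for j, tok in enumerate(tokens):
                if len(tok) not in (4, 6) or not tok.isdigit():
                    raise ValueError(f"bad genotype token {tok!r} for {name!r}")
                half = len(tok) // 2
                row[j] = (int(tok[:half]), int(tok[half:]))
            uniq = name if name not in pop else f"{name}_{len(individuals)}"
            individuals.append(uniq)
            pop[uniq] = pop_name
            rows.append(row)
    return GenotypeMatrix(np.stack(rows), individuals, loci, pop)
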