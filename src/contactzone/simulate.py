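"""Synthetic data generators for every pipeline input.

The generators emulate the structure of a two-lineage secondary-contact
study: a common-garden morphometric design (two parental lines, F1,
backcrosses, F2), a two-haplogroup mtDNA control-region alignment with a
diagnostic restriction site, structured microsatellite genotypes under the
Balding-Nichols model, and a free-female-choice mating experiment with
Mendelian broods.  Every generator is a pure function of its configuration
and seed and returns ground truth alongside the data, so each analysis
stage has an exact recovery target.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from contactzone.morpho_io import (
    LandmarkConfiguration,
    LandmarkDataset,
    write_group_map,
    write_tps,
)
from contactzone.matechoice import Brood
from contactzone.popgen import (
    GenotypeMatrix,
    SequenceAlignment,
    rflp_assign,
    write_fasta_alignment,
    write_genotype_table,
)

# ---------------------------------------------------------------------------
# configuration


@dataclass
class MorphoSimConfig:
    """Common-garden morphometric simulation.

    Shape variation lives in a fixed orthonormal basis of tangent-space
    directions (orthogonal to translation, rotation and scaling of the base
    form), with per-axis score standard deviations decreasing geometrically
    so the generating axes map onto the leading relative warps.  Parental
    lines differ in mean along the first axis; hybrid groups draw their
    scores from mixtures of the parental distributions; a configured true
    range extension is injected into the transgressive groups by affinely
    rescaling their realized scores, so the sample-level extension equals
    the target exactly.
    """

    k: int = 25  # landmarks per specimen
    n_axes: int = 6  # generating shape axes
    score_sd: float = 0.02  # axis-1 score sd (Procrustes units)
    sd_decay: float = 0.8  # geometric decay of per-axis sds
    parent_separation: float = 0.02  # mean difference between parental lines on axis 1
    group_sizes: dict = field(
        default_factory=lambda: {
            "parentA": 25,
            "parentB": 25,
            "F1": 50,
            "backcrossA": 50,
            "backcrossB": 50,
            "F2": 50,
        }
    )
    hybrid_transgression: dict = field(default_factory=lambda: {"RW3": 30.0, "RW5": 40.0})
    transgressive_groups: tuple = ("F2",)
    allometry_slope: float = 0.15  # per-axis slope in score-sd per size-sd units; keeps the size effect under 10% of score variance on every axis
    size_mean: float = 250.0  # centroid size, image pixels
    size_sd: float = 25.0
    digitisation_noise_sd: float = 0.5  # image pixels
    seed: int = 0

    def validate(self) -> None:
        if self.k < 3:
            raise ValueError("k: need at least 3 landmarks")
        if self.score_sd <= 0 or self.digitisation_noise_sd < 0 or self.size_sd <= 0:
            raise ValueError("score_sd/size_sd must be positive; digitisation_noise_sd non-negative")
        if not (0.0 < self.sd_decay <= 1.0):
            raise ValueError("sd_decay: must lie in (0, 1] to keep generating axes ordered")
        if any(v < 2 for v in self.group_sizes.values()):
            raise ValueError("group_sizes: every group needs at least 2 specimens")
        if any(v < 0 for v in self.hybrid_transgression.values()):
            raise ValueError("hybrid_transgression: extensions must be non-negative")


@dataclass
class GeneticSimConfig:
    """Contact-zone genetic simulation (sequences, microsatellites, matings)."""

    # mtDNA control region
    seq_length: int = 403
    divergence_sites: int = 10  # fixed differences between haplogroup ancestors
    private_mutation_rate: float = 1.0  # Poisson mean per individual
    n_per_group: tuple = (105, 105)
    ambiguous_column_rate: float = 0.115  # fraction of columns given a gap/N
    motif: str = "GTTAAC"  # HpaI site carried by group A only

    # microsatellites (Balding-Nichols structured populations)
    n_loci: int = 7
    n_alleles: int = 8
    target_fst: float = 0.15
    pop_sizes: dict = field(
        default_factory=lambda: {"Salima": 50, "Ruvuma": 50, "LiwondeLMC": 50, "LiwondeSEC": 50}
    )

    # mate choice
    assortment: float = 0.8  # probability a female mates within her lineage
    females_per_lineage: int = 6
    males_per_lineage: int = 3
    replicates: int = 4
    fry_per_brood: int = 8
    mc_n_loci: int = 5
    mc_n_alleles: int = 8
    lineage_fst: float = 0.15  # divergence of the two lineages' marker pools

    seed: int = 0

    def validate(self) -> None:
        for name in ("ambiguous_column_rate", "assortment", "target_fst", "lineage_fst"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}: probability {v} outside [0, 1]")
        for name in (
            "seq_length", "divergence_sites", "n_loci", "n_alleles",
            "females_per_lineage", "males_per_lineage", "replicates",
            "fry_per_brood", "mc_n_loci", "mc_n_alleles",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name}: must be a positive count")
        if self.private_mutation_rate < 0:
            raise ValueError("private_mutation_rate: must be non-negative")
        if min(self.n_per_group) < 1:
            raise ValueError("n_per_group: both groups need individuals")


# ---------------------------------------------------------------------------
# landmark generator

_BASES = np.array(list("ACGT"))


def _base_shape(k: int) -> np.ndarray:
    """Deterministic fish-like base form: an elongated outline plus interior points."""
    n_outline = max(3, k - k // 5)
    t = np.linspace(0.0, 2 * np.pi, n_outline, endpoint=False)
    outline = np.column_stack([np.cos(t), 0.45 * np.sin(t)])
    n_inner = k - n_outline
    if n_inner:
        ti = np.linspace(0.3, 2 * np.pi - 0.3, n_inner)
        inner = np.column_stack([0.5 * np.cos(ti), 0.2 * np.sin(ti)])
        pts = np.vstack([outline, inner])
    else:
        pts = outline
    pts -= pts.mean(axis=0)
    return pts / np.sqrt((pts**2).sum())  # unit centroid size


def _generating_basis(base: np.ndarray, n_axes: int) -> np.ndarray:
    """Orthonormal tangent directions, orthogonal to similarity transforms.

    Drawn from a fixed internal stream (independent of the data seed) so
    axis identity is stable across simulated datasets.
    """
    k = base.shape[0]
    flat = base.reshape(-1)
    rot = np.column_stack([-base[:, 1], base[:, 0]]).reshape(-1)
    tx = np.tile([1.0, 0.0], k) / np.sqrt(k)
    ty = np.tile([0.0, 1.0], k) / np.sqrt(k)
    forbidden = np.stack([tx, ty, flat / np.linalg.norm(flat), rot / np.linalg.norm(rot)])

    rng = np.random.default_rng(np.random.SeedSequence([314159, k, n_axes]))
    raw = rng.standard_normal((n_axes, 2 * k))
    basis = []
    for v in raw:
        for f in forbidden:
            v = v - (v @ f) * f
        for b in basis:
            v = v - (v @ b) * b
        v = v / np.linalg.norm(v)
        basis.append(v)
    return np.stack(basis)


def gen_landmarks(cfg: MorphoSimConfig) -> tuple[LandmarkDataset, dict]:
    """Simulate a common-garden landmark dataset with known shape structure.

    Returns the dataset and a truth record holding the generating basis,
    per-specimen true scores and sizes, and the realized per-axis range
    extension of each hybrid group over the pooled parental sample.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    base = _base_shape(cfg.k)
    basis = _generating_basis(base, cfg.n_axes)
    sds = cfg.score_sd * cfg.sd_decay ** np.arange(cfg.n_axes)
    delta = cfg.parent_separation

    def axis1_mean_draw(group: str, size: int) -> np.ndarray:
        """Axis-1 location per specimen; hybrids mix the parental components."""
        half = delta / 2.0
        if group == "parentA":
            return np.full(size, half)
        if group == "parentB":
            return np.full(size, -half)
        if group == "F1":
            return np.zeros(size)
        if group == "backcrossA":
            return rng.choice([half, 0.0], size=size)
        if group == "backcrossB":
            return rng.choice([-half, 0.0], size=size)
        # F2 and wild groups: 50/50 mixture of the parental components
        return rng.choice([half, -half], size=size)

    order = list(cfg.group_sizes)
    groups: list[str] = []
    scores_list = []
    for g in order:
        size = cfg.group_sizes[g]
        s = rng.standard_normal((size, cfg.n_axes)) * sds
        s[:, 0] += axis1_mean_draw(g, size)
        scores_list.append(s)
        groups.extend([g] * size)
    scores = np.vstack(scores_list)
    groups_arr = np.array(groups)

    # inject the configured true range extension by affine rescaling of the
    # transgressive groups' realized scores against the pooled parental sample
    parent_mask = np.isin(groups_arr, ["parentA", "parentB"])
    axis_names = [f"RW{j + 1}" for j in range(cfg.n_axes)]
    for axis_name, pct in cfg.hybrid_transgression.items():
        if axis_name not in axis_names:
            raise ValueError(f"hybrid_transgression axis {axis_name!r} outside RW1..RW{cfg.n_axes}")
        if pct <= 0:
            continue
        j = axis_names.index(axis_name)
        lo, hi = scores[parent_mask, j].min(), scores[parent_mask, j].max()
        span = hi - lo
        ext = pct / 100.0 * span / 2.0
        for g in cfg.transgressive_groups:
            sel = groups_arr == g
            v = scores[sel, j]
            vmin, vmax = v.min(), v.max()
            a = (hi + ext - (lo - ext)) / (vmax - vmin)
            scores[sel, j] = (v - vmin) * a + (lo - ext)

    # realized truth before the allometric component is added
    truth_ext = {}
    for j, axis_name in enumerate(axis_names):
        p = scores[parent_mask, j]
        span = p.max() - p.min()
        for g in order:
            if g in ("parentA", "parentB"):
                continue
            h = scores[groups_arr == g, j]
            upper = max(0.0, h.max() - p.max())
            lower = max(0.0, p.min() - h.min())
            truth_ext[(axis_name, g)] = 100.0 * (upper + lower) / span

    n = scores.shape[0]
    sizes = rng.normal(cfg.size_mean, cfg.size_sd, size=n)
    sizes = np.clip(sizes, cfg.size_mean * 0.3, None)
    allo = cfg.allometry_slope * sds * ((sizes - cfg.size_mean) / cfg.size_sd)[:, None]
    final_scores = scores + allo

    configs = []
    for i in range(n):
        flat = base.reshape(-1) + final_scores[i] @ basis
        shape = flat.reshape(cfg.k, 2)
        theta = rng.uniform(-0.15, 0.15)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        coords = shape @ rot.T * sizes[i]
        coords += rng.uniform(0.0, 100.0, size=2)
        coords += rng.normal(0.0, cfg.digitisation_noise_sd, size=coords.shape)
        configs.append(
            LandmarkConfiguration(specimen_id=f"sp{i:04d}", coords=coords, group=groups[i])
        )

    truth = {
        "basis": basis,
        "axis_names": axis_names,
        "true_scores": scores,
        "sizes": sizes,
        "groups": groups_arr,
        "extension_pct": truth_ext,
        "axis_sds": sds,
    }
    return LandmarkDataset(configs), truth


# ---------------------------------------------------------------------------
# sequence generator


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(0, 3)]
    return out


def gen_sequences(cfg: GeneticSimConfig, max_retries: int = 50) -> tuple[SequenceAlignment, dict]:
    """Simulate a two-haplogroup control-region alignment.

    Group A's ancestor carries the diagnostic restriction motif; group B's
    differs at the stated number of fixed sites, one of which disrupts the
    motif.  Individuals accumulate Poisson private mutations away from the
    diagnostic positions; gap/ambiguity cells are injected column-wise at
    the configured rate, away from diagnostic positions, so site filtering
    removes them without touching the haplogroup signal.  Each individual's
    restriction assignment is verified against truth, regenerating its
    mutations on collision (bounded retries).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    L, w = cfg.seq_length, len(cfg.motif)
    if cfg.divergence_sites < 1:
        raise ValueError("divergence_sites: need at least the motif-disrupting site")
    motif_start = L // 8
    window = set(range(motif_start, motif_start + w))

    for _ in range(max_retries):
        anc_a = _random_seq(rng, L)
        anc_a[motif_start : motif_start + w] = list(cfg.motif)
        if rflp_count("".join(anc_a), cfg.motif) == 1:
            break
    else:
        raise RuntimeError("could not draw an ancestor with a unique motif occurrence")

    # fixed differences: one inside the motif (disrupting it), rest outside
    outside = np.setdiff1d(np.arange(L), sorted(window))
    fixed_outside = rng.choice(outside, size=cfg.divergence_sites - 1, replace=False)
    disrupt_pos = motif_start + 2
    fixed_sites = np.append(fixed_outside, disrupt_pos)
    for _ in range(max_retries):
        anc_b = _mutate(anc_a, fixed_sites, rng)
        if rflp_count("".join(anc_b), cfg.motif) == 0:
            break
    else:
        raise RuntimeError("could not disrupt the motif in the second ancestor")

    protected = window | set(int(p) for p in fixed_sites)
    mutable = np.array(sorted(set(range(L)) - protected))

    records: dict[str, str] = {}
    truth_group: dict[str, str] = {}
    idx = 0
    for group, ancestor, n_ind in (("A", anc_a, cfg.n_per_group[0]), ("B", anc_b, cfg.n_per_group[1])):
        expect = "cut" if group == "A" else "uncut"
        for _ in range(n_ind):
            rid = f"ind{idx:04d}_{group}"
            idx += 1
            for _ in range(max_retries):
                n_mut = rng.poisson(cfg.private_mutation_rate)
                n_mut = min(n_mut, mutable.size)
                pos = rng.choice(mutable, size=n_mut, replace=False) if n_mut else np.array([], int)
                seq = _mutate(ancestor, pos, rng)
                s = "".join(seq)
                if rflp_assign(s, cfg.motif) == expect:
                    records[rid] = s
                    truth_group[rid] = group
                    break
            else:
                raise RuntimeError(f"could not generate a motif-consistent sequence for {rid}")

    # inject gap/ambiguity columns away from diagnostic positions
    ids = list(records)
    n_cols = int(round(cfg.ambiguous_column_rate * L))
    n_cols = min(n_cols, mutable.size)
    noisy_cols = rng.choice(mutable, size=n_cols, replace=False) if n_cols else np.array([], int)
    mat = np.array([list(records[r]) for r in ids])
    for col in noisy_cols:
        n_hit = rng.integers(1, 4)
        hit = rng.choice(len(ids), size=min(n_hit, len(ids)), replace=False)
        mat[hit, col] = rng.choice(["-", "N"])
    aln = SequenceAlignment({rid: "".join(row) for rid, row in zip(ids, mat)})

    truth = {
        "group": truth_group,
        "cut_group": "A",
        "fixed_sites": sorted(int(p) for p in fixed_sites),
        "ambiguous_columns": sorted(int(c) for c in noisy_cols),
        "motif_start": motif_start,
        "ancestors": {"A": "".join(anc_a), "B": "".join(anc_b)},
    }
    return aln, truth


def rflp_count(seq: str, motif: str) -> int:
    """Number of motif occurrences (helper for generator sanity checks)."""
    count = start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def gen_screen_sequences(cfg: GeneticSimConfig, n: int = 400, max_retries: int = 50) -> tuple[dict, dict]:
    """Clean (gap/N-free) sequences for the diagnostic restriction screen.

    Emulates the contact-zone screening panel: individuals from both
    haplogroups in roughly equal numbers, with private mutations, suitable
    for direct restriction typing.  Returns sequences and true haplogroups.
    """
    sub = dataclasses.replace(
        cfg,
        n_per_group=(n - n // 2, n // 2),
        ambiguous_column_rate=0.0,
        seed=cfg.seed + 1,
    )
    aln, truth = gen_sequences(sub, max_retries=max_retries)
    return dict(aln.records), truth["group"]


# ---------------------------------------------------------------------------
# microsatellite generator


def _balding_nichols_freqs(
    rng: np.random.Generator, n_alleles: int, fst: float, n_pops: int
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral and per-population allele frequencies under Balding-Nichols."""
    p = rng.dirichlet(np.ones(n_alleles))
    if fst <= 1e-9:
        pops = np.tile(p, (n_pops, 1))
    else:
        scale = (1.0 - fst) / fst
        pops = np.stack([rng.dirichlet(np.maximum(p * scale, 1e-9)) for _ in range(n_pops)])
    return p, pops


def gen_genotypes(cfg: GeneticSimConfig) -> tuple[GenotypeMatrix, dict]:
    """Simulate structured diploid microsatellite genotypes.

    Per-locus population allele frequencies follow the Balding-Nichols
    model at the configured target FST; genotypes are two independent
    draws from the population frequency vector.
    """
    cfg.validate()
    if not (0.0 <= cfg.target_fst < 1.0):
        raise ValueError("target_fst: must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    pops = list(cfg.pop_sizes)
    n_total = sum(cfg.pop_sizes.values())
    genos = np.zeros((n_total, cfg.n_loci, 2), dtype=int)
    individuals: list[str] = []
    pop_of: dict[str, str] = {}
    ancestral = np.zeros((cfg.n_loci, cfg.n_alleles))
    pop_freqs = np.zeros((cfg.n_loci, len(pops), cfg.n_alleles))
    for locus in range(cfg.n_loci):
        ancestral[locus], pop_freqs[locus] = _balding_nichols_freqs(
            rng, cfg.n_alleles, cfg.target_fst, len(pops)
        )
    row = 0
    for pi, pop in enumerate(pops):
        for j in range(cfg.pop_sizes[pop]):
            ind = f"{pop}_{j:03d}"
            individuals.append(ind)
            pop_of[ind] = pop
            for locus in range(cfg.n_loci):
                genos[row, locus] = (
                    rng.choice(cfg.n_alleles, size=2, p=pop_freqs[locus, pi]) + 1
                )
            row += 1
    loci = [f"loc{l + 1}" for l in range(cfg.n_loci)]
    g = GenotypeMatrix(genos, individuals, loci, pop_of)
    truth = {"ancestral_freqs": ancestral, "pop_freqs": pop_freqs, "populations": pops}
    return g, truth


# ---------------------------------------------------------------------------
# mate-choice generator


@dataclass
class MateChoiceData:
    broods: list
    candidates: dict[str, np.ndarray]
    candidate_lineage: dict[str, str]
    candidate_replicate: dict[str, str]
    mother_lineage: dict[str, str]
    true_sire: dict[str, str]

    def candidates_for(self, replicate_id: str) -> dict[str, np.ndarray]:
        return {
            cid: g
            for cid, g in self.candidates.items()
            if self.candidate_replicate[cid] == replicate_id
        }


def gen_matechoice(cfg: GeneticSimConfig) -> MateChoiceData:
    """Simulate a free-female-choice experiment with Mendelian broods.

    Each replicate houses fresh males from both lineages; each female mates
    within her lineage with the configured assortment probability, choosing
    uniformly among that lineage's males; fry inherit one maternal and one
    paternal allele per locus.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    lineages = ("Salima", "Ruvuma")
    freqs = np.zeros((cfg.mc_n_loci, 2, cfg.mc_n_alleles))
    for locus in range(cfg.mc_n_loci):
        _, freqs[locus] = _balding_nichols_freqs(rng, cfg.mc_n_alleles, cfg.lineage_fst, 2)

    def draw_genotype(lineage_idx: int) -> np.ndarray:
        g = np.zeros((cfg.mc_n_loci, 2), dtype=int)
        for locus in range(cfg.mc_n_loci):
            g[locus] = rng.choice(cfg.mc_n_alleles, size=2, p=freqs[locus, lineage_idx]) + 1
        return g

    broods = []
    candidates: dict[str, np.ndarray] = {}
    candidate_lineage: dict[str, str] = {}
    candidate_replicate: dict[str, str] = {}
    mother_lineage: dict[str, str] = {}
    true_sire: dict[str, str] = {}

    for rep in range(1, cfg.replicates + 1):
        rep_id = str(rep)
        males: dict[str, list[str]] = {lin: [] for lin in lineages}
        for li, lin in enumerate(lineages):
            for m in range(cfg.males_per_lineage):
                mid = f"r{rep}_male_{lin}_{m}"
                candidates[mid] = draw_genotype(li)
                candidate_lineage[mid] = lin
                candidate_replicate[mid] = rep_id
                males[lin].append(mid)
        for li, lin in enumerate(lineages):
            for f in range(cfg.females_per_lineage):
                bid = f"r{rep}_brood_{lin}_{f}"
                mother = draw_genotype(li)
                homotypic = rng.random() < cfg.assortment
                sire_lin = lin if homotypic else lineages[1 - li]
                sire_id = males[sire_lin][rng.integers(0, cfg.males_per_lineage)]
                sire = candidates[sire_id]
                fry = np.zeros((cfg.fry_per_brood, cfg.mc_n_loci, 2), dtype=int)
                for i in range(cfg.fry_per_brood):
                    for locus in range(cfg.mc_n_loci):
                        fry[i, locus, 0] = mother[locus, rng.integers(0, 2)]
                        fry[i, locus, 1] = sire[locus, rng.integers(0, 2)]
                broods.append(
                    Brood(
                        brood_id=bid,
                        mother_id=f"{bid}_mother",
                        mother=mother,
                        fry=fry,
                        replicate_id=rep_id,
                    )
                )
                mother_lineage[bid] = lin
                true_sire[bid] = sire_id

    return MateChoiceData(
        broods=broods,
        candidates=candidates,
        candidate_lineage=candidate_lineage,
        candidate_replicate=candidate_replicate,
        mother_lineage=mother_lineage,
        true_sire=true_sire,
    )


# ---------------------------------------------------------------------------
# run directory with manifest


def load_config(path: str | Path) -> tuple[MorphoSimConfig, GeneticSimConfig]:
    """Read a YAML config with optional ``morpho:`` and ``genetics:`` sections."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    morpho = MorphoSimConfig(**raw.get("morpho", {}))
    genetics = GeneticSimConfig(**raw.get("genetics", {}))
    if "seed" in raw:
        morpho.seed = genetics.seed = int(raw["seed"])
    morpho.validate()
    genetics.validate()
    return morpho, genetics


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_matechoice_tables(data: MateChoiceData, broods_path: Path, candidates_path: Path) -> None:
    import pandas as pd

    loci = [f"loc{l + 1}" for l in range(data.broods[0].mother.shape[0])]
    rows = []
    for b in data.broods:
        row = {
            "brood_id": b.brood_id, "replicate": b.replicate_id, "role": "mother",
            "individual": b.mother_id, "lineage": data.mother_lineage[b.brood_id],
        }
        row.update({f"{l}.{k + 1}": b.mother[j, k] for j, l in enumerate(loci) for k in (0, 1)})
        rows.append(row)
        for i in range(b.fry.shape[0]):
            row = {
                "brood_id": b.brood_id, "replicate": b.replicate_id, "role": "fry",
                "individual": f"{b.brood_id}_fry{i}", "lineage": "",
            }
            row.update({f"{l}.{k + 1}": b.fry[i, j, k] for j, l in enumerate(loci) for k in (0, 1)})
            rows.append(row)
    pd.DataFrame(rows).to_csv(broods_path, sep="\t", index=False)

    crows = []
    for cid, g in data.candidates.items():
        row = {
            "individual": cid, "lineage": data.candidate_lineage[cid],
            "replicate": data.candidate_replicate[cid],
        }
        row.update({f"{l}.{k + 1}": g[j, k] for j, l in enumerate(loci) for k in (0, 1)})
        crows.append(row)
    pd.DataFrame(crows).to_csv(candidates_path, sep="\t", index=False)


def simulate_run(
    morpho_cfg: MorphoSimConfig, genetic_cfg: GeneticSimConfig, outdir: str | Path
) -> dict:
    """Generate all pipeline inputs into a run directory with a manifest.

    Writes TPS landmarks + group sidecar, the two-haplogroup FASTA
    alignment, the screening panel, the microsatellite genotype table and
    the mate-choice tables, plus a JSON truth record and a manifest with
    file hashes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    dataset, morpho_truth = gen_landmarks(morpho_cfg)
    write_tps(dataset, outdir / "landmarks.tps")
    write_group_map({c.specimen_id: c.group for c in dataset}, outdir / "groups.tsv")

    aln, seq_truth = gen_sequences(genetic_cfg)
    write_fasta_alignment(aln, outdir / "control_region.fasta")
    screen, screen_truth = gen_screen_sequences(genetic_cfg)
    write_fasta_alignment(SequenceAlignment(screen), outdir / "screen_panel.fasta")

    genotypes, geno_truth = gen_genotypes(genetic_cfg)
    write_genotype_table(genotypes, outdir / "microsatellites.tsv")

    mc = gen_matechoice(genetic_cfg)
    write_matechoice_tables(mc, outdir / "broods.tsv", outdir / "candidates.tsv")

    truth = {
        "morpho_extension_pct": {f"{a}|{g}": v for (a, g), v in morpho_truth["extension_pct"].items()},
        "haplogroup": seq_truth["group"],
        "screen_haplogroup": screen_truth,
        "true_sire": mc.true_sire,
        "seeds": {"morpho": morpho_cfg.seed, "genetics": genetic_cfg.seed},
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))

    files = sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json")
    manifest = {
        "files": {name: _sha256(outdir / name) for name in files},
        "config": {
            "morpho": dataclasses.asdict(morpho_cfg),
            "genetics": dataclasses.asdict(genetic_cfg),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
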