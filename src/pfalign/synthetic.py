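"""Synthetic homologous profile pairs with known ground-truth alignments.

The generator emulates remote-homolog profile pairs: an ancestral profile of
sparse Dirichlet PSSVs diverges along two independent lineages through
per-site substitution noise (a bounded Dirichlet perturbation, renormalized to
the simplex) and insertion/deletion segments with geometric lengths.  The
surviving ancestral sites define the true residue-to-residue homology map,
returned as the reference alignment.

Default parameters are chosen so that a default pair lands at roughly 10-30%
sequence identity, the remote-homolog ("twilight zone") regime.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Tuple

import numpy as np

from .profiles import (
    GAP,
    RESIDUE_ORDER,
    PairwiseAlignment,
    Profile,
    write_pairwise_fasta_alignment,
    write_pssm,
)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the divergence process.

    seed: master RNG seed (identical config => byte-identical output).
    length: ancestral profile length.
    substitution_noise: per-site perturbation weight tau >= 0; each inherited
        PSSV becomes (ancestor + tau * Dirichlet draw) / (1 + tau).
    indel_rate: per-site probability of starting an indel event per lineage
        (half deletions, half insertions).
    mean_indel_length: mean of the geometric segment-length law (>= 1).
    concentration: symmetric Dirichlet concentration of ancestral (and
        inserted) PSSVs; small values give realistically peaked columns.
    """

    seed: int = 0
    length: int = 120
    substitution_noise: float = 1.3
    indel_rate: float = 0.04
    mean_indel_length: float = 3.0
    concentration: float = 0.3

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        if self.substitution_noise < 0:
            raise ValueError("substitution_noise must be >= 0")
        if not (0 <= self.indel_rate < 1):
            raise ValueError("indel_rate must be in [0, 1)")
        if self.mean_indel_length < 1:
            raise ValueError("mean_indel_length must be >= 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")


def random_pssv(rng: np.random.Generator, concentration: float) -> np.ndarray:
    """Draw one PSSV from a symmetric Dirichlet over the 20 amino acids."""
    if concentration <= 0:
        raise ValueError(f"concentration must be > 0, got {concentration}")
    return rng.dirichlet(np.full(20, concentration))


def random_pssv_block(
    rng: np.random.Generator, concentration: float, n: int
) -> np.ndarray:
    """Draw n PSSVs at once (rows on the simplex)."""
    if concentration <= 0:
        raise ValueError(f"concentration must be > 0, got {concentration}")
    return rng.dirichlet(np.full(20, concentration), size=n)


def _sequence_from_vectors(vectors: np.ndarray) -> str:
    # argmax takes the first maximum, i.e. ties break by canonical order
    return "".join(RESIDUE_ORDER[k] for k in np.argmax(vectors, axis=1))


def _perturb(rng: np.random.Generator, pssv: np.ndarray, tau: float, conc: float) -> np.ndarray:
    if tau == 0:
        return pssv
    noise = random_pssv(rng, conc)
    return (pssv + tau * noise) / (1.0 + tau)


def _geometric_length(rng: np.random.Generator, mean: float) -> int:
    # geometric on {1, 2, ...} with mean `mean`
    return int(rng.geometric(1.0 / mean))


def _evolve_lineage(
    rng: np.random.Generator, ancestor: np.ndarray, cfg: SynthConfig
) -> Tuple[np.ndarray, np.ndarray, List[List[np.ndarray]]]:
    """Apply substitution noise and indels to one descendant lineage.

    Returns (vectors of inherited sites, survival mask over ancestral sites,
    inserted novel PSSVs per slot; slot t holds insertions placed before
    ancestral site t, slot L the tail insertions).
    """
    L = len(ancestor)
    half = cfg.indel_rate / 2.0
    deleted = np.zeros(L, dtype=bool)
    for i in range(L):
        if rng.random() < half:
            k = _geometric_length(rng, cfg.mean_indel_length)
            deleted[i : i + k] = True
    inserts: List[List[np.ndarray]] = [[] for _ in range(L + 1)]
    for slot in range(L + 1):
        if rng.random() < half:
            k = _geometric_length(rng, cfg.mean_indel_length)
            inserts[slot] = [
                random_pssv(rng, cfg.concentration) for _ in range(k)
            ]
    inherited = np.array(
        [
            _perturb(rng, ancestor[i], cfg.substitution_noise, cfg.concentration)
            for i in range(L)
            if not deleted[i]
        ]
    ).reshape(-1, 20)
    return inherited, ~deleted, inserts


def generate_profile_pair(
    config: SynthConfig, _retries: int = 20
) -> Tuple[Profile, Profile, PairwiseAlignment]:
    """Generate two descendant profiles plus the true reference alignment.

    The reference contains one column per surviving ancestral site: aligned if
    the site survives in both lineages, a gap column if in exactly one;
    lineage-specific insertions appear as gap columns on their own side.
    """
    for attempt in range(_retries):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed), attempt])
        )
        ancestor = random_pssv_block(rng, config.concentration, config.length)
        vec_a, keep_a, ins_a = _evolve_lineage(rng, ancestor, config)
        vec_b, keep_b, ins_b = _evolve_lineage(rng, ancestor, config)
        if len(vec_a) + sum(map(len, ins_a)) == 0:
            continue
        if len(vec_b) + sum(map(len, ins_b)) == 0:
            continue
        return _assemble_pair(config, vec_a, keep_a, ins_a, vec_b, keep_b, ins_b)
    raise RuntimeError(
        f"config {config} deleted an entire sequence in {_retries} attempts"
    )


def _assemble_pair(config, vec_a, keep_a, ins_a, vec_b, keep_b, ins_b):
    rows_a: List[np.ndarray] = []
    rows_b: List[np.ndarray] = []
    columns: List[Tuple[int, int]] = []
    ia = ib = 0  # next inherited-site row in vec_a / vec_b
    pa = pb = 0  # next site index in descendant A / B
    L = len(keep_a)

    def emit_inserts(slot):
        nonlocal pa, pb
        for v in ins_a[slot]:
            rows_a.append(v)
            columns.append((pa, GAP))
            pa += 1
        for v in ins_b[slot]:
            rows_b.append(v)
            columns.append((GAP, pb))
            pb += 1

    for t in range(L):
        emit_inserts(t)
        in_a, in_b = keep_a[t], keep_b[t]
        if in_a and in_b:
            rows_a.append(vec_a[ia])
            rows_b.append(vec_b[ib])
            columns.append((pa, pb))
            ia += 1
            ib += 1
            pa += 1
            pb += 1
        elif in_a:
            rows_a.append(vec_a[ia])
            columns.append((pa, GAP))
            ia += 1
            pa += 1
        elif in_b:
            rows_b.append(vec_b[ib])
            columns.append((GAP, pb))
            ib += 1
            pb += 1
    emit_inserts(L)

    mat_a = np.array(rows_a).reshape(-1, 20)
    mat_b = np.array(rows_b).reshape(-1, 20)
    prof_a = Profile(
        id=f"synth{config.seed}_a",
        sequence=_sequence_from_vectors(mat_a),
        vectors=mat_a,
    )
    prof_b = Profile(
        id=f"synth{config.seed}_b",
        sequence=_sequence_from_vectors(mat_b),
        vectors=mat_b,
    )
    ref = PairwiseAlignment(id_a=prof_a.id, id_b=prof_b.id, columns=tuple(columns))
    return prof_a, prof_b, ref


def derive_pair_seeds(master_seed: int, n_pairs: int) -> List[int]:
    """Deterministic, pairwise-distinct per-pair seeds below 2**31."""
    state = np.random.SeedSequence(master_seed).generate_state(n_pairs, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def generate_dataset(
    config_template: SynthConfig, n_pairs: int, seed: int
) -> List[Tuple[Profile, Profile, PairwiseAlignment]]:
    """Generate n_pairs independent triples with seeds derived from `seed`."""
    if n_pairs < 1:
        raise ValueError(f"n_pairs must be >= 1, got {n_pairs}")
    triples = []
    for k, pair_seed in enumerate(derive_pair_seeds(seed, n_pairs)):
        cfg = replace(config_template, seed=pair_seed)
        a, b, ref = generate_profile_pair(cfg)
        a = Profile(id=f"pair{k:04d}_a", sequence=a.sequence, vectors=a.vectors)
        b = Profile(id=f"pair{k:04d}_b", sequence=b.sequence, vectors=b.vectors)
        ref = PairwiseAlignment(id_a=a.id, id_b=b.id, columns=ref.columns)
        triples.append((a, b, ref))
    return triples


def reference_identity(a: Profile, b: Profile, ref: PairwiseAlignment) -> float:
    """Fraction of aligned reference columns with identical residue letters."""
    pairs = [(i, j) for i, j in ref.columns if i is not None and j is not None]
    if not pairs:
        return 0.0
    same = sum(1 for i, j in pairs if a.sequence[i] == b.sequence[j])
    return same / len(pairs)


def write_dataset(
    triples: List[Tuple[Profile, Profile, PairwiseAlignment]], outdir
) -> Path:
    """Write PSSM, FASTA and reference-alignment files plus a manifest.

    Returns the manifest path.  Manifest columns: pair id, PSSM A, PSSM B,
    reference alignment path, true identity percent.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["pair\tpssm_a\tpssm_b\treference\tidentity_pct"]
    for a, b, ref in triples:
        stem = a.id.rsplit("_", 1)[0]
        pa, pb = outdir / f"{a.id}.pssm", outdir / f"{b.id}.pssm"
        pr = outdir / f"{stem}_ref.fasta"
        write_pssm(a, pa)
        write_pssm(b, pb)
        write_pairwise_fasta_alignment(ref, a.sequence, b.sequence, pr)
        fasta = outdir / f"{stem}.fasta"
        fasta.write_text(f">{a.id}\n{a.sequence}\n>{b.id}\n{b.sequence}\n")
        ident = 100.0 * reference_identity(a, b, ref)
        lines.append(f"{stem}\t{pa.name}\t{pb.name}\t{pr.name}\t{ident:.1f}")
    manifest = outdir / "manifest.tsv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
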