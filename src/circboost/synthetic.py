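"""Self-consistent synthetic inputs with planted block structure.

Entities (circRNAs and diseases) are assigned round-robin to latent
functional blocks. circRNAs in a block share an embedded sequence motif, a
core set of GO terms, and a block-mean expression profile; diseases in a
block share a core gene set and sit under a common ontology subtree.
Associations are sampled cell-wise Bernoulli with a higher probability for
block-matched pairs. Everything is a deterministic function of the seed.

The default scale mirrors a curated circRNA-disease benchmark: 132
circRNAs, 40 diseases, 32 expression sites, and Bernoulli rates chosen so
the expected association count is ~140.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import io as cio
from .io import AssociationMatrix, ExpressionMatrix, OntologyDAG

__all__ = ["SynthConfig", "SyntheticBundle", "generate", "write_bundle"]


@dataclass(frozen=True)
class SynthConfig:
    n_circ: int = 132
    n_disease: int = 40
    n_blocks: int = 5
    seq_len: tuple[int, int] = (150, 300)
    n_sites: int = 32
    go_universe: int = 1000
    genes_universe: int = 500
    within_block_assoc_prob: float = 0.13
    between_block_assoc_prob: float = 0.001
    noise_sd: float = 0.3
    seed: int = 0
    # secondary structure knobs
    motif_len: int = 6
    go_core: int = 15
    go_random: int = 5
    genes_core: int = 20
    genes_random: int = 5

    def __post_init__(self) -> None:
        if self.n_blocks > min(self.n_circ, self.n_disease):
            raise ValueError("n_blocks must be <= min(n_circ, n_disease)")
        w, b = self.within_block_assoc_prob, self.between_block_assoc_prob
        if not (0.0 <= b <= w <= 1.0):
            raise ValueError(
                "association probabilities out of order: need "
                "0 <= between <= within <= 1"
            )
        if self.seq_len[0] < self.motif_len or self.seq_len[0] > self.seq_len[1]:
            raise ValueError("invalid seq_len range")
        if self.go_universe < self.n_blocks * self.go_core:
            raise ValueError("go_universe too small for the block core sets")
        if self.genes_universe < self.n_blocks * self.genes_core:
            raise ValueError("genes_universe too small for the block core sets")


@dataclass
class SyntheticBundle:
    """In-memory bundle of all generated inputs."""

    config: SynthConfig
    seqs: dict[str, str]
    go_annotations: dict[str, set[str]]
    go_universe_size: int
    expression: ExpressionMatrix
    disease_genes: dict[str, set[str]]
    ontology: OntologyDAG
    disease_terms: dict[str, str]
    associations: AssociationMatrix   # full n_circ x n_disease matrix
    circ_blocks: np.ndarray
    disease_blocks: np.ndarray


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[k] for k in rng.integers(0, 4, size=length))


def generate(cfg: SynthConfig | None = None) -> SyntheticBundle:
    """Generate the full input bundle from the configuration seed."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    circ_ids = [f"circ{i:04d}" for i in range(cfg.n_circ)]
    disease_ids = [f"dis{j:03d}" for j in range(cfg.n_disease)]
    circ_blocks = np.arange(cfg.n_circ) % cfg.n_blocks
    disease_blocks = np.arange(cfg.n_disease) % cfg.n_blocks

    # --- sequences: random background + one planted motif per block
    motifs: list[str] = []
    while len(motifs) < cfg.n_blocks:
        m = _random_seq(rng, cfg.motif_len)
        if m not in motifs:
            motifs.append(m)
    seqs: dict[str, str] = {}
    for i, c in enumerate(circ_ids):
        length = int(rng.integers(cfg.seq_len[0], cfg.seq_len[1] + 1))
        seq = list(_random_seq(rng, length))
        pos = int(rng.integers(0, length - cfg.motif_len + 1))
        seq[pos : pos + cfg.motif_len] = motifs[circ_blocks[i]]
        seqs[c] = "".join(seq)

    # --- GO annotations: disjoint block cores plus random extras
    universe = [f"GO:{t:07d}" for t in range(cfg.go_universe)]
    cores = [
        set(universe[b * cfg.go_core : (b + 1) * cfg.go_core])
        for b in range(cfg.n_blocks)
    ]
    pool = universe[cfg.n_blocks * cfg.go_core :]
    go_annot: dict[str, set[str]] = {}
    for i, c in enumerate(circ_ids):
        extra = rng.choice(len(pool), size=min(cfg.go_random, len(pool)), replace=False)
        go_annot[c] = set(cores[circ_blocks[i]]) | {pool[k] for k in extra}

    # --- expression: block mean + Gaussian noise
    block_means = rng.normal(0.0, 1.0, size=(cfg.n_blocks, cfg.n_sites))
    expr = block_means[circ_blocks] + rng.normal(
        0.0, cfg.noise_sd, size=(cfg.n_circ, cfg.n_sites)
    )
    expression = ExpressionMatrix(
        list(circ_ids), [f"site{s:02d}" for s in range(cfg.n_sites)], expr
    )

    # --- disease genes
    gene_universe = [f"G{t:05d}" for t in range(cfg.genes_universe)]
    gene_cores = [
        set(gene_universe[b * cfg.genes_core : (b + 1) * cfg.genes_core])
        for b in range(cfg.n_blocks)
    ]
    gene_pool = gene_universe[cfg.n_blocks * cfg.genes_core :]
    disease_genes: dict[str, set[str]] = {}
    for j, d in enumerate(disease_ids):
        extra = rng.choice(
            len(gene_pool), size=min(cfg.genes_random, len(gene_pool)), replace=False
        )
        disease_genes[d] = set(gene_cores[disease_blocks[j]]) | {
            gene_pool[k] for k in extra
        }

    # --- ontology: root -> block nodes -> one leaf term per disease
    terms = {"T:root"}
    edges: list[tuple[str, str]] = []
    for b in range(cfg.n_blocks):
        node = f"T:block{b}"
        terms.add(node)
        edges.append((node, "T:root"))
    disease_terms: dict[str, str] = {}
    for j, d in enumerate(disease_ids):
        leaf = f"T:{d}"
        terms.add(leaf)
        edges.append((leaf, f"T:block{disease_blocks[j]}"))
        disease_terms[d] = leaf
    ontology = OntologyDAG(terms, edges)

    # --- associations: cell-wise Bernoulli, block-dependent rate
    match = circ_blocks[:, None] == disease_blocks[None, :]
    prob = np.where(match, cfg.within_block_assoc_prob, cfg.between_block_assoc_prob)
    values = (rng.random((cfg.n_circ, cfg.n_disease)) < prob).astype(float)
    associations = AssociationMatrix(list(circ_ids), list(disease_ids), values)

    return SyntheticBundle(
        config=cfg,
        seqs=seqs,
        go_annotations=go_annot,
        go_universe_size=cfg.go_universe,
        expression=expression,
        disease_genes=disease_genes,
        ontology=ontology,
        disease_terms=disease_terms,
        associations=associations,
        circ_blocks=circ_blocks,
        disease_blocks=disease_blocks,
    )


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict:
    """Write every input file and return a manifest (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "sequences": "sequences.fasta",
        "go_annotations": "circ_go.tsv",
        "expression": "expression.tsv",
        "disease_genes": "disease_genes.tsv",
        "ontology": "ontology.tsv",
        "disease_terms": "disease_terms.tsv",
        "associations": "associations.tsv",
    }
    cio.write_fasta(bundle.seqs, out / files["sequences"])
    cio.write_annotations(bundle.go_annotations, out / files["go_annotations"])
    cio.write_matrix(bundle.expression, out / files["expression"])
    cio.write_annotations(bundle.disease_genes, out / files["disease_genes"])
    cio.write_ontology(bundle.ontology, out / files["ontology"])
    with open(out / files["disease_terms"], "w", encoding="utf-8") as fh:
        fh.write("disease_id\tterm_id\n")
        for d in sorted(bundle.disease_terms):
            fh.write(f"{d}\t{bundle.disease_terms[d]}\n")
    cio.write_associations(bundle.associations, out / files["associations"])
    manifest = {
        "seed": bundle.config.seed,
        "go_universe_size": bundle.go_universe_size,
        "files": files,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(bundle.config).items()
        },
    }
    cio.write_json(manifest, out / "manifest.json")
    return manifest
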