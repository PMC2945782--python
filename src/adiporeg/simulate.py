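"""Synthetic inputs with known ground truth for every pipeline stage.

Three seeded simulators emulate the study's data types:

* ``simulate_expression`` — a log2-scale expression matrix over the nine
  condition cells (day 3 untreated; days 6 and 11 under control, CD2314,
  BIO, CD2314+BIO), three replicates each, with genes planted into the
  five CD2314-response clusters at configurable effect sizes and i.i.d.
  Gaussian replicate noise.
* ``simulate_genome`` — chromosome FASTA + TSS BED + conservation
  bedGraph for a promoter universe in which a chosen PWM occurs at an
  elevated rate in foreground promoters, with elevated conservation at
  planted sites (instances are sampled from the PWM's column
  distributions, not the consensus).
* ``simulate_ppi`` — a human interaction edge list plus a human->mouse
  ortholog table with a controlled fraction of ambiguous (zero or
  many-to-one) mappings, and a truth table of the edges that survive the
  one-to-one ortholog rule.

Each simulator is driven by one ``numpy.random.default_rng`` seed,
recorded in the output file headers, and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import COMPARATORS, TESTED_TIME_POINTS
from .motifs import BASES, PWM

__all__ = [
    "default_design",
    "ExpressionSimConfig",
    "simulate_expression",
    "GenomeSimConfig",
    "simulate_genome",
    "simulate_ppi",
    "random_pwm",
    "shuffle_pwm_columns",
    "write_jaspar",
]


# ---------------------------------------------------------------------------
# expression

def default_design() -> pd.DataFrame:
    """The 9-condition x 3-replicate sample sheet (27 samples).

    Day 3 has a single untreated cell (labelled control); days 6 and 11
    each have all four treatment arms.
    """
    rows = []
    cells = [("d3", "control")] + [
        (tp, tr)
        for tp in TESTED_TIME_POINTS
        for tr in ("control", "CD2314", "BIO", "CD2314+BIO")
    ]
    for tp, tr in cells:
        for rep in (1, 2, 3):
            rows.append((f"{tp}_{tr}_r{rep}", tp, tr))
    return pd.DataFrame(rows, columns=["sample_id", "time_point", "treatment"])


@dataclass
class ExpressionSimConfig:
    """Planted-signal configuration for the expression simulator.

    ``n_per_cluster`` genes are planted into each of clusters 1-5 with
    the given |log2 fold-change| (sign per cluster definition: clusters
    1/3/5 up, 2/4 down).  ``n_confounded`` extra genes receive the day-6
    effect in CD2314 *and* one rotating comparator arm, so they differ
    from only two of the three comparators and must never be assigned.
    """

    n_per_cluster: dict[int, int] = field(
        default_factory=lambda: {c: 200 for c in range(1, 6)}
    )
    effect_day6: float = 2.0
    effect_day11: float = 2.0
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    n_confounded: int = 0


_CLUSTER_SIGN = {1: +1, 2: -1, 3: +1, 4: -1, 5: +1}
_CLUSTER_DAYS = {1: ("d6",), 2: ("d6",), 3: ("d11",), 4: ("d11",), 5: ("d6", "d11")}


def simulate_expression(
    n_genes: int,
    design: pd.DataFrame | None = None,
    config: ExpressionSimConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a genes x samples log2 expression matrix with planted clusters.

    Returns ``(matrix, truth)``; truth has one row per gene with its
    planted cluster (0 = none), per-day effects, noise level and, for
    confounded genes, the comparator arm sharing the effect.
    """
    design = default_design() if design is None else design
    config = config or ExpressionSimConfig()
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if config.noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    needed = {(tp, tr) for tp in TESTED_TIME_POINTS
              for tr in ("CD2314",) + COMPARATORS}
    have = set(zip(design["time_point"], design["treatment"]))
    if not needed <= have:
        raise ValueError(f"design missing conditions: {sorted(needed - have)}")

    n_planted = sum(config.n_per_cluster.values()) + config.n_confounded
    if n_planted > n_genes:
        raise ValueError("more planted genes than n_genes")

    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    samples = design["sample_id"].tolist()
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)
    values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(n_genes, len(samples))
    )

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "planted_cluster": 0,
            "effect_day6": 0.0,
            "effect_day11": 0.0,
            "noise_sd": config.noise_sd,
            "confounded_with": "",
        }
    )

    tp_arr = design["time_point"].to_numpy()
    tr_arr = design["treatment"].to_numpy()

    def _cols(tp: str, treatments: tuple[str, ...]) -> np.ndarray:
        return np.flatnonzero((tp_arr == tp) & np.isin(tr_arr, treatments))

    idx = 0
    for cluster in sorted(config.n_per_cluster):
        count = config.n_per_cluster[cluster]
        sign = _CLUSTER_SIGN[cluster]
        for _ in range(count):
            for day in _CLUSTER_DAYS[cluster]:
                eff = config.effect_day6 if day == "d6" else config.effect_day11
                values[idx, _cols(day, ("CD2314",))] += sign * eff
                truth.loc[idx, f"effect_{'day6' if day == 'd6' else 'day11'}"] = sign * eff
            truth.loc[idx, "planted_cluster"] = cluster
            idx += 1
    for j in range(config.n_confounded):
        shared = COMPARATORS[j % len(COMPARATORS)]
        values[idx, _cols("d6", ("CD2314", shared))] += config.effect_day6
        truth.loc[idx, "effect_day6"] = config.effect_day6
        truth.loc[idx, "confounded_with"] = shared
        idx += 1

    matrix = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                          columns=samples)
    return matrix, truth


# ---------------------------------------------------------------------------
# genome / promoters

@dataclass
class GenomeSimConfig:
    """Motif-planting configuration for the promoter-universe simulator.

    Unplanted sequence is i.i.d. over A/C/G/T with ``base_freqs``.
    Background conservation is drawn per ``cons_block`` bp block from a
    Beta(``cons_beta``) distribution (default mean 0.25, so most windows
    fail the masked modes); on top of that every promoter, foreground or
    background alike, receives a Poisson(``conserved_element_rate``)
    number of conserved elements of ``conserved_element_length`` bp with
    values uniform on ``conserved_element_range`` — phastCons-style
    conserved islands, so that *having* conserved sequence is
    uninformative about cluster membership and only the planted motif
    separates the groups.  Planted motif positions get the constant
    ``conservation_at_plant``.
    """

    foreground_rate: float = 0.4
    background_rate: float = 0.05
    conservation_at_plant: float = 0.95
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    cons_beta: tuple[float, float] = (1.0, 3.0)
    cons_block: int = 10
    conserved_element_rate: float = 4.0
    conserved_element_length: int = 30
    conserved_element_range: tuple[float, float] = (0.7, 1.0)


def _sample_motif_instance(pwm: PWM, rng: np.random.Generator) -> str:
    freqs = pwm.frequencies()
    return "".join(
        BASES[rng.choice(4, p=freqs[:, j] / freqs[:, j].sum())]
        for j in range(pwm.width)
    )


_RC = str.maketrans("ACGT", "TGCA")
_BASE_BYTES = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)


def simulate_genome(
    n_foreground: int,
    n_background: int,
    planted_pwm: PWM,
    config: GenomeSimConfig | None = None,
    seed: int = 0,
    outdir: str | Path = ".",
    promoter_length: int = 3000,
    foreground_ids: Sequence[str] | None = None,
    background_ids: Sequence[str] | None = None,
    genes_per_chrom: int = 200,
    spacer: int = 500,
) -> dict[str, Path | pd.DataFrame]:
    """Emit genome FASTA, TSS BED6, conservation bedGraph and a truth table.

    One promoter region of ``promoter_length`` bp per gene, strands
    alternating so both are represented; the TSS sits so that one third
    of the region is downstream (2,000/1,000 at the default length).
    Foreground genes carry a planted motif instance with probability
    ``foreground_rate``, background genes with ``background_rate``; the
    truth table records every planted position (promoter-oriented offset
    and genomic interval).

    Returns a dict with the three file paths and the truth DataFrame.
    """
    config = config or GenomeSimConfig()
    if n_foreground <= 0 or n_background < 0:
        raise ValueError("n_foreground must be positive, n_background >= 0")
    for rate in (config.foreground_rate, config.background_rate):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("occurrence rates must lie in [0, 1]")
    if planted_pwm.width > promoter_length:
        raise ValueError("motif wider than promoter")
    downstream = promoter_length // 3
    upstream = promoter_length - downstream

    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    n_genes = n_foreground + n_background
    if foreground_ids is None:
        foreground_ids = [f"fg{i:05d}" for i in range(n_foreground)]
    if background_ids is None:
        background_ids = [f"bg{i:05d}" for i in range(n_background)]
    if len(foreground_ids) != n_foreground or len(background_ids) != n_background:
        raise ValueError("gene id lists must match the requested counts")
    gene_ids = list(foreground_ids) + list(background_ids)
    is_fg = np.arange(n_genes) < n_foreground

    region = promoter_length + spacer
    base_p = np.asarray(config.base_freqs, dtype=float)
    if not np.isclose(base_p.sum(), 1.0) or np.any(base_p < 0):
        raise ValueError("base_freqs must be non-negative and sum to 1")

    chroms: dict[str, list[str]] = {}
    bed_rows = []
    cons_rows = []  # (chrom, start, end, value)
    truth_rows = []
    for g in range(n_genes):
        chrom = f"chr{g // genes_per_chrom + 1}"
        slot = g % genes_per_chrom
        rs = slot * region  # promoter region start on this chromosome
        strand = "+" if g % 2 == 0 else "-"
        tss = rs + upstream if strand == "+" else rs + promoter_length - upstream - 1

        codes = rng.choice(4, size=promoter_length, p=base_p)
        seq = bytes(_BASE_BYTES[codes]).decode("ascii")

        # block-wise background conservation over the promoter region
        n_blocks = -(-promoter_length // config.cons_block)
        block_vals = rng.beta(*config.cons_beta, size=n_blocks)
        cons = np.repeat(block_vals, config.cons_block)[:promoter_length]
        # conserved islands at the same rate in every promoter
        elen = config.conserved_element_length
        for _ in range(rng.poisson(config.conserved_element_rate)):
            es = int(rng.integers(0, max(1, promoter_length - elen + 1)))
            cons[es : es + elen] = rng.uniform(*config.conserved_element_range)

        rate = config.foreground_rate if is_fg[g] else config.background_rate
        has_motif = bool(rng.random() < rate)
        offset = -1
        if has_motif:
            offset = int(rng.integers(0, promoter_length - planted_pwm.width + 1))
            inst = _sample_motif_instance(planted_pwm, rng)
            if strand == "+":
                gstart = rs + offset
                piece = inst
            else:
                gstart = rs + promoter_length - offset - planted_pwm.width
                piece = inst.translate(_RC)[::-1]
            seq = seq[: gstart - rs] + piece + seq[gstart - rs + planted_pwm.width :]
            lo = gstart - rs
            cons[lo : lo + planted_pwm.width] = config.conservation_at_plant
            truth_rows.append(
                (gene_ids[g], chrom, strand, bool(is_fg[g]), True, offset,
                 gstart, gstart + planted_pwm.width)
            )
        else:
            truth_rows.append(
                (gene_ids[g], chrom, strand, bool(is_fg[g]), False, -1, -1, -1)
            )

        chroms.setdefault(chrom, [])
        # pad with spacer of fixed 'A' runs (outside any promoter window)
        chroms[chrom].append(seq + "A" * spacer)
        bed_rows.append((chrom, tss, tss + 1, gene_ids[g], 0, strand))
        # emit conservation as merged constant runs
        breaks = np.flatnonzero(np.diff(cons)) + 1
        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [promoter_length]))
        for s, e in zip(starts, ends):
            cons_rows.append((chrom, rs + int(s), rs + int(e), cons[s]))

    header = f"# adiporeg simulate_genome seed={seed}\n"
    fasta_path = outdir / "genome.fa"
    with open(fasta_path, "w") as fh:
        for chrom in sorted(chroms, key=lambda c: int(c[3:])):
            full = "".join(chroms[chrom])
            fh.write(f">{chrom} adiporeg_simulated seed={seed}\n")
            for i in range(0, len(full), 60):
                fh.write(full[i : i + 60] + "\n")

    bed_path = outdir / "tss.bed"
    with open(bed_path, "w") as fh:
        fh.write(header)
        for row in bed_rows:
            fh.write("\t".join(map(str, row)) + "\n")

    cons_path = outdir / "conservation.bedGraph"
    with open(cons_path, "w") as fh:
        fh.write(header)
        for chrom, s, e, v in cons_rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.4f}\n")

    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "chrom", "strand", "is_foreground", "has_motif",
                 "offset", "site_start", "site_end"],
    )
    truth_path = outdir / "genome_truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write(header)
        truth.to_csv(fh, sep="\t", index=False)
    return {
        "fasta": fasta_path,
        "tss": bed_path,
        "conservation": cons_path,
        "truth_path": truth_path,
        "truth": truth,
        "upstream": upstream,
        "downstream": downstream,
    }


# ---------------------------------------------------------------------------
# protein-protein interactions

def simulate_ppi(
    n_human_proteins: int,
    n_edges: int,
    frac_ambiguous_orthologs: float,
    seed: int = 0,
    mouse_id_pool: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Simulate a human PPI edge list and a human->mouse ortholog table.

    Each human protein maps to exactly one mouse id, except an
    ``frac_ambiguous_orthologs`` fraction that alternately map to two
    mouse ids or to none; either way such proteins fail the one-to-one
    rule.  The truth table marks which edges survive the rule and what
    mouse edge they become.  Loops are allowed (sampled once each).

    ``mouse_id_pool`` optionally supplies the mouse gene names used for
    unambiguous mappings (e.g. to tie the network to simulated expression
    gene ids); it must be at least as long as the number of unambiguous
    proteins.
    """
    if n_human_proteins <= 0 or n_edges <= 0:
        raise ValueError("protein and edge counts must be positive")
    if not 0.0 <= frac_ambiguous_orthologs <= 1.0:
        raise ValueError("frac_ambiguous_orthologs must lie in [0, 1]")
    max_edges = n_human_proteins * (n_human_proteins + 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"n_edges exceeds possible pairs ({max_edges})")

    rng = np.random.default_rng(seed)
    humans = [f"h{i:05d}" for i in range(n_human_proteins)]

    n_ambiguous = int(round(frac_ambiguous_orthologs * n_human_proteins))
    ambiguous = {
        int(i) for i in rng.choice(n_human_proteins, size=n_ambiguous, replace=False)
    }
    unambiguous = [i for i in range(n_human_proteins) if i not in ambiguous]
    if mouse_id_pool is not None:
        if len(mouse_id_pool) < len(unambiguous):
            raise ValueError("mouse_id_pool smaller than the unambiguous protein set")
        pool = list(mouse_id_pool)[: len(unambiguous)]
    else:
        pool = [f"m{i:05d}" for i in unambiguous]
    mouse_of = {i: m for i, m in zip(unambiguous, pool)}

    ortho_rows = []
    for rank, i in enumerate(sorted(ambiguous)):
        if rank % 2 == 0:  # many-to-one: two mouse ids
            ortho_rows.append((humans[i], f"mx{i:05d}a"))
            ortho_rows.append((humans[i], f"mx{i:05d}b"))
        # odd ranks: no mouse ortholog at all -> no row
    for i in unambiguous:
        ortho_rows.append((humans[i], mouse_of[i]))
    orthologs = pd.DataFrame(ortho_rows, columns=["human_id", "mouse_id"])

    # sample distinct unordered pairs (loops allowed) by linear pair index
    pair_idx = rng.choice(max_edges, size=n_edges, replace=False)
    edges = []
    for idx in sorted(pair_idx):
        # idx -> (i, j), i <= j, enumerating rows of the upper triangle
        i = int((np.sqrt(8 * idx + 1) - 1) // 2)
        # fix possible off-by-one from float sqrt
        while (i + 1) * (i + 2) // 2 <= idx:
            i += 1
        while i * (i + 1) // 2 > idx:
            i -= 1
        j = idx - i * (i + 1) // 2
        edges.append((humans[i], humans[j]))

    truth_rows = []
    for a, b in edges:
        ia, ib = int(a[1:]), int(b[1:])
        survives = ia not in ambiguous and ib not in ambiguous
        if survives:
            ma, mb = mouse_of[ia], mouse_of[ib]
            mouse_edge = (ma, mb) if ma <= mb else (mb, ma)
        else:
            mouse_edge = ("", "")
        truth_rows.append((a, b, survives, mouse_edge[0], mouse_edge[1]))

    edges_df = pd.DataFrame(edges, columns=["protein_a", "protein_b"])
    truth = pd.DataFrame(
        truth_rows,
        columns=["protein_a", "protein_b", "survives", "mouse_a", "mouse_b"],
    )
    return {"edges": edges_df, "orthologs": orthologs, "truth": truth}


# ---------------------------------------------------------------------------
# PWM helpers

def random_pwm(
    motif_id: str, width: int = 10, seed: int = 0, concentration: float = 0.5,
    total: int = 100,
) -> PWM:
    """An informative random PWM: Dirichlet columns scaled to integer counts."""
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet([concentration] * 4, size=width).T
    counts = np.round(probs * total)
    counts[3, :] = total - counts[:3, :].sum(axis=0)  # exact column sums
    counts = np.clip(counts, 0, None)
    return PWM(motif_id=motif_id, counts=counts)


def shuffle_pwm_columns(pwm: PWM, seed: int, motif_id: str | None = None) -> PWM:
    """Decoy PWM: same columns in a seeded random order.

    Keeps per-column information content while destroying the planted
    site structure, the standard negative control for motif recovery.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pwm.width)
    return PWM(
        motif_id=motif_id or f"{pwm.motif_id}_shuf{seed}",
        counts=pwm.counts[:, perm],
        source=pwm.source,
        background=pwm.background,
        pseudocount=pwm.pseudocount,
    )


def write_jaspar(pwms: Sequence[PWM], path: str | Path) -> Path:
    """Write PWMs as a multi-record JASPAR PFM collection."""
    path = Path(path)
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.motif_id}\n")
            for bi, base in enumerate(BASES):
                vals = " ".join(f"{v:.0f}" if float(v).is_integer() else f"{v:g}"
                                for v in pwm.counts[bi])
                fh.write(f"{base} [ {vals} ]\n")
    return path
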