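"""Synthetic cohorts with the statistical structure the pipeline assumes.

Every generator is a pure function of (parameters, seed) and returns a
truth record listing all planted memberships, so downstream sensitivity
and false-discovery rates can be scored without re-reading parameters.

``simulate_counts`` emulates a platelet spliced-RNA cohort: negative-
binomially distributed intron-spanning counts over a few thousand genes
(the platelet repertoire is roughly 4,000-5,000 spliced RNAs), log-normal
library sizes in the shallow-sequencing range, a fraction of genes with a
group fold-change, a subset of depth-tracking "stable" genes, an additive
latent batch factor on the log scale, and an age-coupled gene subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CountMatrix, SampleAnnotation
from .rbp_engine import RBPMotifSet, UTRRecord, count_motif_hits
from .splice_events import PSIMatrix


@dataclass
class ConfounderSpec:
    """Strengths of the planted nuisance structure.

    ``batch_strength`` is the standard deviation of the additive batch
    term on the natural-log scale (0 disables it); ``batch_frac`` the
    fraction of genes loading on it.  ``age_strength`` couples a gene
    subset to donor age (log-scale coefficient per age SD);
    ``stable_frac`` sets how many genes are sampled tightly proportional
    to library size (the negative-control truth).
    """

    batch_strength: float = 0.5
    batch_frac: float = 1.0
    age_strength: float = 0.4
    age_frac: float = 0.05
    stable_frac: float = 0.1
    stable_dispersion: float = 0.005


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB draw with variance mu + phi mu**2 (gamma-Poisson mixture)."""
    if phi <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam)


def simulate_counts(
    n_genes: int = 4500,
    n_samples: int = 263,
    frac_de: float = 0.1,
    logfc: float = 1.0,
    dispersion: float = 0.2,
    confounders: ConfounderSpec | None = None,
    mean_lib_size: float = 7.5e5,
    lib_size_sd: float = 0.35,
    seed: int = 0,
    roles: tuple[float, float, float] = (0.35, 0.15, 0.5),
) -> tuple[CountMatrix, SampleAnnotation, dict]:
    """Two-group NB cohort with planted effects and confounders.

    Half of the differential genes go up by ``2**logfc`` in the disease
    group, half down.  Stable genes are drawn nearly noise-free around
    their library-size-proportional expectation and carry no group,
    batch, or age effect.  Returns (counts, annotation, truth).
    """
    if not (0 <= frac_de <= 1):
        raise ValueError("frac_de must be in [0, 1]")
    conf = confounders or ConfounderSpec()
    rng = np.random.default_rng(seed)

    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"S{i:04d}" for i in range(n_samples)]

    # baseline relative abundance (log-normal), normalized to proportions
    base = rng.lognormal(mean=1.2, sigma=1.4, size=n_genes)
    prop = base / base.sum()

    lib = rng.lognormal(np.log(mean_lib_size), lib_size_sd, size=n_samples)

    group = np.array(["non-cancer", "cancer"])[
        (np.arange(n_samples) % 2 == 1).astype(int)
    ]
    is_case = group == "cancer"
    age = np.round(rng.normal(60.0, 10.0, size=n_samples), 1)

    # disjoint planted gene sets: stable first, then DE / batch / age on the rest
    perm = rng.permutation(n_genes)
    n_stable = int(round(conf.stable_frac * n_genes))
    stable_idx = perm[:n_stable]
    rest = perm[n_stable:]
    n_de = int(round(frac_de * n_genes))
    n_de = min(n_de, rest.size)
    de_idx = rest[:n_de]
    up_idx = de_idx[: n_de // 2]
    down_idx = de_idx[n_de // 2:]
    n_age = int(round(conf.age_frac * n_genes))
    age_idx = rest[n_de: n_de + n_age]

    log_mu = np.log(np.outer(prop, lib))  # genes x samples
    log_mu[np.ix_(up_idx, is_case)] += logfc * np.log(2.0)
    log_mu[np.ix_(down_idx, is_case)] -= logfc * np.log(2.0)

    # the latent batch loads on the stable genes too: negative-control
    # genes must carry the unwanted variation (that is what lets the
    # factor model see it) while staying free of biology (group, age)
    batch = rng.standard_normal(n_samples)
    batch_idx = np.array([], dtype=int)
    if conf.batch_strength > 0 and conf.batch_frac > 0:
        if conf.batch_frac >= 1.0:
            batch_idx = np.arange(n_genes)
        else:
            n_batch = int(round(conf.batch_frac * n_genes))
            pool = np.concatenate([stable_idx, rest[n_de + n_age:]])
            batch_idx = pool[: min(n_batch, pool.size)]
        loadings = np.abs(rng.normal(1.0, 0.25, size=batch_idx.size))
        log_mu[batch_idx] += conf.batch_strength * np.outer(loadings, batch)

    if conf.age_strength > 0 and n_age > 0:
        z_age = (age - age.mean()) / max(age.std(), 1e-9)
        log_mu[age_idx] += conf.age_strength * z_age[None, :]

    mu = np.exp(log_mu)
    counts = _nb_sample(rng, mu, dispersion)
    # stable genes: tight NB around their (depth- and batch-scaled) mean,
    # so they track the realized library size almost noise-free
    counts[stable_idx] = _nb_sample(
        rng, mu[stable_idx], conf.stable_dispersion
    )

    matrix = CountMatrix(
        pd.DataFrame(counts.astype(np.int64), index=genes, columns=samples)
    )
    role = np.empty(n_samples, dtype=object)
    n_train = int(round(roles[0] * n_samples))
    n_eval = int(round(roles[1] * n_samples))
    # alternate groups within each role block so roles stay class-balanced
    role[:n_train] = "training"
    role[n_train: n_train + n_eval] = "evaluation"
    role[n_train + n_eval:] = "validation"
    ann = SampleAnnotation(
        pd.DataFrame(
            {
                "group": group,
                "age": age,
                "storage": np.where(rng.random(n_samples) < 0.9, "<12hr", ">12hr"),
                "gender": rng.choice(["f", "m"], size=n_samples),
                "smoking": rng.choice(
                    ["current", "former", "never", "unknown"], size=n_samples
                ),
                "cohort_role": role,
                "site": "synthetic",
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    gene_arr = np.asarray(genes)
    truth = {
        "de_genes": list(gene_arr[de_idx]),
        "up_genes": list(gene_arr[up_idx]),
        "down_genes": list(gene_arr[down_idx]),
        "stable_genes": list(gene_arr[stable_idx]),
        "batch_genes": list(gene_arr[batch_idx]),
        "age_genes": list(gene_arr[age_idx]),
        "batch_scores": pd.Series(batch, index=samples),
        "lib_size": pd.Series(lib, index=samples),
        "dispersion": dispersion,
        "logfc": logfc,
    }
    return matrix, ann, truth


# ---------------------------------------------------------------------------
# UTR / motif fixture
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, forbidden: list[str]) -> str:
    """Random sequence free of any forbidden substring (rejection sampling)."""
    for _ in range(200):
        seq = "".join(rng.choice(_BASES, size=length))
        if not any(f in seq for f in forbidden):
            return seq
    raise RuntimeError("could not scrub forbidden motifs from a random sequence")


@dataclass
class UTRFixture:
    records: list[UTRRecord]
    logfc: pd.Series
    truth: dict
    genome: dict[str, str] = field(default_factory=dict)
    gtf_lines: list[str] = field(default_factory=list)

    def write(self, outdir) -> dict:
        """Write genome.fa, annotation.gtf, coverage.tsv, logfc.tsv."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        fa = out / "genome.fa"
        with fa.open("w") as fh:
            for contig, seq in self.genome.items():
                fh.write(f">{contig}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i: i + 70] + "\n")
        gtf = out / "annotation.gtf"
        gtf.write_text("\n".join(self.gtf_lines) + "\n")
        cov = out / "coverage.tsv"
        pd.DataFrame(
            [
                (r.transcript_id, r.side, r.read_count)
                for r in self.records
            ],
            columns=["transcript_id", "side", "read_count"],
        ).to_csv(cov, sep="\t", index=False)
        lf = out / "logfc.tsv"
        self.logfc.rename("logFC").to_csv(lf, sep="\t")
        return {"genome": fa, "gtf": gtf, "coverage": cov, "logfc": lf}


def simulate_utr_fixture(
    motif_sets: list[RBPMotifSet],
    planted_rbp: str,
    effect: float = 1.0,
    n_genes: int = 100,
    utr3_len: int = 240,
    utr5_len: int = 90,
    frac_covered: float = 0.85,
    seed: int = 0,
) -> UTRFixture:
    """Plant binding sites of one RBP proportionally to per-gene fold-change.

    Each gene gets a single-exon plus-strand transcript (5' UTR, CDS,
    3' UTR on its own contig).  The planted RBP's motifs are inserted in
    the 3' UTR, ``round(effect * max(logFC, 0)) + Poisson noise`` copies,
    into background sequence scrubbed of accidental matches, so scanning
    the generated sequence recovers the inserted count exactly.
    """
    by_id = {ms.rbp_id: ms for ms in motif_sets}
    if planted_rbp not in by_id:
        raise ValueError(f"planted RBP {planted_rbp!r} not in the motif set")
    planted = by_id[planted_rbp]
    forbidden = planted.expanded
    rng = np.random.default_rng(seed)

    records: list[UTRRecord] = []
    genome: dict[str, str] = {}
    gtf: list[str] = []
    logfc = {}
    planted_counts = {}
    for i in range(n_genes):
        gene = f"G{i:04d}"
        tx = f"T{i:04d}"
        contig = f"chr_{gene}"
        lfc = float(rng.normal(0.0, 1.0))
        logfc[gene] = lfc
        n_insert = 0
        if effect > 0:
            n_insert = int(max(0, round(effect * max(lfc, 0.0))))
            n_insert += int(rng.poisson(0.3))
        motifs = [
            planted.expanded[j]
            for j in rng.integers(0, len(planted.expanded), size=n_insert)
        ]
        # spacer / motif / spacer ... construction; spacers are scrubbed and
        # the whole UTR re-drawn if a junction accidentally creates a match
        for _ in range(50):
            pieces = [_random_seq(rng, 12, forbidden)]
            for mseq in motifs:
                pieces.append(mseq)
                pieces.append(_random_seq(rng, 12, forbidden))
            fill = utr3_len - sum(len(p) for p in pieces)
            if fill > 0:
                pieces.append(_random_seq(rng, fill, forbidden))
            utr3 = "".join(pieces)
            if count_motif_hits(utr3, planted.expanded) == n_insert:
                break
        else:
            raise RuntimeError("could not assemble a 3' UTR with the exact count")
        utr5 = _random_seq(rng, utr5_len, forbidden)
        cds = _random_seq(rng, 150, [])
        seq = utr5 + cds + utr3
        genome[contig] = seq
        # GTF is 1-based inclusive
        cds_start, cds_end = len(utr5) + 1, len(utr5) + len(cds)
        attrs = f'gene_id "{gene}"; transcript_id "{tx}";'
        gtf.append(
            f"{contig}\tsyn\ttranscript\t1\t{len(seq)}\t.\t+\t.\t{attrs}"
        )
        gtf.append(f"{contig}\tsyn\texon\t1\t{len(seq)}\t.\t+\t.\t{attrs}")
        gtf.append(
            f"{contig}\tsyn\tCDS\t{cds_start}\t{cds_end}\t.\t+\t0\t{attrs}"
        )
        cov5 = int(rng.integers(3, 40)) if rng.random() < frac_covered else int(rng.integers(0, 3))
        cov3 = int(rng.integers(5, 60)) if rng.random() < frac_covered else int(rng.integers(0, 5))
        records.append(UTRRecord(gene, tx, "five_prime", utr5, cov5))
        records.append(UTRRecord(gene, tx, "three_prime", utr3, cov3))
        planted_counts[gene] = n_insert

    return UTRFixture(
        records=records,
        logfc=pd.Series(logfc, name="logFC"),
        truth={
            "planted_rbp": planted_rbp,
            "planted_counts": planted_counts,
            "effect": effect,
        },
        genome=genome,
        gtf_lines=gtf,
    )


# ---------------------------------------------------------------------------
# PSI fixture
# ---------------------------------------------------------------------------


def simulate_psi_fixture(
    n_events: int = 200,
    n_samples: int = 100,
    frac_shifted: float = 0.2,
    delta: float = 0.3,
    concentration: float = 60.0,
    mean_total_reads: float = 60.0,
    seed: int = 0,
) -> tuple[PSIMatrix, pd.Series, dict]:
    """Beta-distributed PSI values with a planted group shift.

    Event-level baseline PSI is drawn Beta(2, 2); per-sample PSI is drawn
    around the (possibly shifted) group mean with the given concentration;
    inclusion/exclusion read counts are binomial given PSI and a Poisson
    total-reads draw.  Returns (matrix, group labels, truth).
    """
    if not (-1 <= delta <= 1):
        raise ValueError("delta must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    events = [f"E{i:04d}" for i in range(n_events)]
    samples = [f"S{i:04d}" for i in range(n_samples)]
    group = pd.Series(
        np.array(["non-cancer", "cancer"])[(np.arange(n_samples) % 2).astype(int)],
        index=samples,
    )
    is_case = (group == "cancer").to_numpy()

    base = rng.beta(2.0, 2.0, size=n_events) * 0.8 + 0.1
    n_shift = int(round(frac_shifted * n_events))
    shifted = rng.permutation(n_events)[:n_shift]
    mean = np.tile(base[:, None], (1, n_samples))
    mean[np.ix_(shifted, np.where(is_case)[0])] = np.clip(
        base[shifted, None] + delta, 0.02, 0.98
    )
    a = mean * concentration
    b = (1.0 - mean) * concentration
    psi = rng.beta(a, b)
    total = rng.poisson(mean_total_reads, size=(n_events, n_samples)) + 2
    inclusion = rng.binomial(total, psi)
    exclusion = total - inclusion
    mat = PSIMatrix(
        psi=pd.DataFrame(psi, index=events, columns=samples),
        inclusion=pd.DataFrame(inclusion, index=events, columns=samples),
        exclusion=pd.DataFrame(exclusion, index=events, columns=samples),
    )
    truth = {
        "shifted_events": [events[i] for i in shifted],
        "delta": delta,
    }
    return mat, group, truth
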