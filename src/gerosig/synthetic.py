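"""Synthetic multi-study DEG data with planted ground truth.

The generator emulates the input side of the whole meta-analysis: a signed
"aging program" of genes whose expression shifts with age, recapitulated
by chronic-inflammation models and by the young heterochronic parabiont,
and *reversed* by geroprotective interventions.  Each simulated context
draws log2 fold-changes as role-sign x planted effect plus Gaussian noise,
with p-values from the known noise model so that null genes are exactly
uniform and BH-FDR behavior is testable.

It also plants: gene sets enriched for program genes (for the
over-representation stages), a marker/expression fixture with known
ambient contaminants (for the single-cell hygiene filter), and count
matrices constructed to invert a given linear transcriptomic clock
exactly.

Gene symbols are synthetic (``G000001``...), uppercase and unique; the
clock fixture uses mouse-style/human-style symbol pairs to exercise
homolog mapping.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import ambient
from .clock import (ClockModel, ClockTransform, ExpressionMatrix,
                    write_clock_model)
from .sig_io import (ContextKey, GerosigError, SignatureTable, SignedGeneList,
                     GeneSetLibrary, bh_adjust, write_gene_list, write_gmt,
                     write_manifest, write_signature_table)

#: role -> multiplier applied to the planted aging effect
DEFAULT_REVERSAL_MAP = {"AGING": 1, "CI": 1, "YPAR": 1, "GI": -1, "OTHER": 0}

#: planted program effects have at least this |log2FC|: the program stands
#: in for a curated list of robustly differential aging genes, so
#: sub-threshold effects would make membership meaningless
MIN_PROGRAM_EFFECT = float(np.log2(1.5))


def _context_rng(seed: int, context: ContextKey, salt: int = 0) -> np.random.Generator:
    """Deterministic per-context generator (stable across processes)."""
    return np.random.default_rng(
        [seed & 0x7FFFFFFF, zlib.crc32(context.label.encode()), salt])


@dataclass
class GroundTruth:
    """Planted structure shared by all simulated contexts."""

    effects: pd.Series  # program gene -> signed log2 effect
    genes: tuple  # full gene universe
    reversal_map: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REVERSAL_MAP))
    noise_sd: float = 0.2
    seed: int = 0
    planted_sets: dict = field(default_factory=dict)  # set id -> PlantedSet
    clock: ClockModel | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise GerosigError("noise_sd must be >= 0")
        stray = set(self.effects.index) - set(self.genes)
        if stray:
            raise GerosigError("program genes outside gene universe")

    @property
    def program_genes(self) -> pd.Index:
        return self.effects.index

    @property
    def n_background_genes(self) -> int:
        return len(self.genes) - len(self.effects)

    def aging_reference(self) -> SignedGeneList:
        """The planted program as a signed global-aging-genes list."""
        return SignedGeneList(
            frozenset(self.effects.index[self.effects > 0]),
            frozenset(self.effects.index[self.effects < 0]))


@dataclass(frozen=True)
class PlantedSet:
    members: frozenset
    direction: str  # "up", "down" or "mixed"
    planted_frac: float


def generate_ground_truth(
    n_genes: int,
    n_program: int,
    effect_sd: float = 1.0,
    seed: int = 0,
    noise_sd: float = 0.2,
    min_effect: float = MIN_PROGRAM_EFFECT,
) -> GroundTruth:
    """Draw a gene universe and a signed aging program.

    Effect magnitudes are ``min_effect + |Normal(0, effect_sd)|`` with a
    uniformly random sign, so effects are symmetric about zero while every
    program gene carries a robust (detectable) fold-change, emulating a
    curated reference list of aging DEGs.
    """
    if not 0 < n_program <= n_genes:
        raise GerosigError("need 0 < n_program <= n_genes")
    if effect_sd <= 0:
        raise GerosigError("effect_sd must be > 0")
    rng = np.random.default_rng(seed)
    genes = tuple(f"G{i:06d}" for i in range(1, n_genes + 1))
    program = sorted(rng.choice(n_genes, size=n_program, replace=False))
    signs = rng.choice([-1.0, 1.0], size=n_program)
    mags = min_effect + np.abs(rng.normal(0.0, effect_sd, size=n_program))
    effects = pd.Series(signs * mags,
                        index=pd.Index([genes[i] for i in program]))
    return GroundTruth(effects, genes, dict(DEFAULT_REVERSAL_MAP),
                       noise_sd, seed)


def simulate_signature(
    truth: GroundTruth,
    context: ContextKey,
    n_samples_equiv: int = 1,
    seed: int | None = None,
) -> SignatureTable:
    """Simulate one context's DEG table from the planted program.

    log2FC = reversal_map[role] x effect + Normal(0, se) for program genes
    and Normal(0, se) otherwise, with se = noise_sd / sqrt(n_samples_equiv).
    P-values are the two-sided normal tail of the observed log2FC under the
    noise model, so null genes give exactly uniform p; the BH column is
    filled by adjustment across all genes.
    """
    if context.role not in truth.reversal_map:
        raise GerosigError(f"role {context.role!r} not in reversal map")
    mult = truth.reversal_map[context.role]
    se = truth.noise_sd / np.sqrt(n_samples_equiv)
    rng = _context_rng(truth.seed if seed is None else seed, context)
    genes = pd.Index(truth.genes)
    signal = mult * truth.effects.reindex(genes, fill_value=0.0).to_numpy()
    log2fc = signal + (rng.normal(0.0, se, size=len(genes)) if se > 0
                       else np.zeros(len(genes)))
    if se > 0:
        p = 2.0 * stats.norm.sf(np.abs(log2fc) / se)
    else:
        p = np.where(log2fc != 0.0, 0.0, 1.0)
    df = pd.DataFrame({"gene": genes, "log2fc": log2fc, "pvalue": p,
                       "fdr": bh_adjust(p)})
    return SignatureTable(context, df)


def simulate_all_signatures(
    truth: GroundTruth,
    contexts: Sequence[ContextKey],
    seed: int | None = None,
) -> dict[ContextKey, SignatureTable]:
    return {c: simulate_signature(truth, c, seed=seed) for c in contexts}


def simulate_gene_sets(
    truth: GroundTruth,
    n_sets: int = 30,
    set_size: int = 40,
    planted_frac: float = 0.5,
    seed: int | None = None,
    n_planted: int | None = None,
    signed: bool = True,
) -> GeneSetLibrary:
    """Plant gene sets enriched for program genes among uniform null sets.

    Planted sets draw a fraction of their members from program genes —
    alternating between the up- and down-program halves when ``signed``,
    emulating direction-coherent pathways (e.g. inflammation up with age)
    — and the rest uniformly from non-program genes.  ``planted_frac`` is
    the fraction of the strongest set; subsequent planted sets grade down
    geometrically to ~28% of it, so scores spread from saturated to
    borderline the way real enrichment strength does.  Null sets are uniform draws from the whole universe, which is
    also the background.  Planted composition is recorded in
    ``truth.planted_sets``.
    """
    if not 0 <= planted_frac <= 1:
        raise GerosigError("planted_frac must lie in [0, 1]")
    if set_size > len(truth.genes):
        raise GerosigError("set_size exceeds gene universe")
    if n_planted is None:
        n_planted = max(1, (2 * n_sets) // 5)
    if n_planted > n_sets:
        raise GerosigError("n_planted exceeds n_sets")
    rng = np.random.default_rng(
        truth.seed if seed is None else seed)
    universe = np.array(truth.genes)
    program = truth.effects.index.to_numpy()
    nonprog = np.array(sorted(set(truth.genes) - set(program)))
    up = truth.effects.index[truth.effects > 0].to_numpy()
    down = truth.effects.index[truth.effects < 0].to_numpy()
    sets: dict[str, frozenset] = {}
    truth.planted_sets = {}
    fracs = planted_frac * np.geomspace(1.0, 0.28, n_planted)
    for i in range(n_planted):
        direction = ("up", "down")[i % 2] if signed else "mixed"
        pool = {"up": up, "down": down, "mixed": program}[direction]
        n_from_prog = int(round(fracs[i] * set_size))
        if n_from_prog > len(pool):
            raise GerosigError(
                f"planted draw needs {n_from_prog} genes, pool has {len(pool)}")
        members = list(rng.choice(pool, size=n_from_prog, replace=False))
        members += list(rng.choice(nonprog, size=set_size - n_from_prog,
                                   replace=False))
        sid = f"PLANTED_{direction.upper()}_{i + 1:02d}"
        sets[sid] = frozenset(members)
        truth.planted_sets[sid] = PlantedSet(sets[sid], direction,
                                             float(fracs[i]))
    for i in range(n_sets - n_planted):
        members = rng.choice(universe, size=set_size, replace=False)
        sets[f"NULL_{i + 1:02d}"] = frozenset(members)
    return GeneSetLibrary(sets, frozenset(truth.genes))


# ---------------------------------------------------------------------------
# default study layout
# ---------------------------------------------------------------------------

def default_contexts() -> list[ContextKey]:
    """The simulated study layout: four interventions (2-4 contexts each),
    bulk and single-cell aging references, the young parabiont, and three
    chronic-inflammation models (bulk + single-cell each)."""
    ctx = []
    for unit in ("liver", "lung"):
        ctx.append(ContextKey("senolysis", "treated-vs-old", unit,
                              "bulk", "GI", "senolysis"))
    for unit in ("liver", "muscle", "wat"):
        ctx.append(ContextKey("cr", "cr-vs-adlib", unit,
                              "bulk", "GI", "caloric_restriction"))
    for unit in ("liver", "pancreas"):
        ctx.append(ContextKey("reprogramming", "oskm-vs-control", unit,
                              "bulk", "GI", "reprogramming"))
    sc_units = ("hepatocyte", "endothelial", "kupffer", "tcell")
    for unit in sc_units:
        ctx.append(ContextKey("parabiosis", "opar-vs-oiso", unit,
                              "single_cell", "GI", "parabiosis"))
    for unit in sc_units:
        ctx.append(ContextKey("parabiosis", "ypar-vs-yiso", unit,
                              "single_cell", "YPAR", "parabiosis"))
    for unit in ("liver", "lung", "muscle"):
        ctx.append(ContextKey("tms-bulk", "old-vs-young", unit,
                              "bulk", "AGING", ""))
    for unit in ("hepatocyte", "endothelial", "kupffer"):
        ctx.append(ContextKey("tms-sc", "old-vs-young", unit,
                              "single_cell", "AGING", ""))
    for study, unit in (("fibrosis", "lung"), ("nash", "liver"),
                        ("nephropathy", "kidney")):
        ctx.append(ContextKey(study, "disease-vs-control", unit,
                              "bulk", "CI", ""))
    for study, unit in (("fibrosis-sc", "epithelial"), ("nash-sc", "hepatocyte"),
                        ("nephropathy-sc", "tubular")):
        ctx.append(ContextKey(study, "disease-vs-control", unit,
                              "single_cell", "CI", ""))
    return ctx


# ---------------------------------------------------------------------------
# clock fixture
# ---------------------------------------------------------------------------

def make_test_clock(
    n_genes: int = 8,
    seed: int = 0,
    intercept: float = 40.0,
    coef_sd: float = 2.0,
) -> ClockModel:
    """A small synthetic linear clock over human-style gene symbols."""
    rng = np.random.default_rng(seed)
    genes = [f"CLK{i:03d}" for i in range(1, n_genes + 1)]
    mags = np.abs(rng.normal(0.0, coef_sd, size=n_genes))
    mags[mags < 0.75] = 0.75  # keep every gene informative
    # balanced signs, as in real clocks: genes whose expression rises or
    # falls with age both carry weight, so ages on either side of the
    # intercept are expressible with nonnegative abundances
    signs = np.where(np.arange(n_genes) % 2 == 0, 1.0, -1.0)
    return ClockModel(intercept, pd.Series(mags * signs,
                                           index=pd.Index(genes)))


def clock_homolog_map(clock: ClockModel) -> pd.DataFrame:
    """Mouse-style (title-case) to human-style symbol map for a clock.

    Includes the simulated filler gene so mapped matrices keep their full
    library size.
    """
    targets = list(clock.coefficients.index) + ["FILLER0"]
    sources = [t.capitalize() for t in targets]
    return pd.DataFrame({"source": sources, "target": targets})


def simulate_clock_expression(
    clock: ClockModel,
    true_ages: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_names: Sequence[str] | None = None,
    groups: Sequence[str] | None = None,
    mouse_symbols: bool = False,
) -> ExpressionMatrix:
    """Construct a counts matrix whose clock readout equals ``true_ages``.

    The linear model is solved per sample: each sample's transformed
    expression is the convex combination of the two extreme admissible
    configurations (every clock gene at the floor or ceiling of its
    transformed range, oriented by coefficient sign) whose clock readouts
    bracket the target age — linearity makes the readout exact.  The
    transform is then inverted to abundances, and a filler gene absorbs
    the remaining library so every sample totals one million counts with
    1 kb gene lengths, making the FPKM of each clock gene equal its
    constructed abundance.  With ``noise_sd = 0`` the full
    map -> normalize -> apply protocol returns ``true_ages`` exactly.
    Gaussian noise (count units) is added to clock-gene counts otherwise.
    Ages outside the range the clock can express with nonnegative
    abundances are an error.
    """
    ages = np.asarray(true_ages, dtype=float)
    if (ages < 0).any():
        raise GerosigError("ages must be >= 0")
    coef = clock.coefficients[clock.coefficients != 0]
    c = coef.to_numpy()
    tf = clock.transform
    # floor keeps counts comfortably above zero (additive noise stays a
    # small log-scale perturbation); ceiling keeps the clock genes a minor
    # fraction of the 1e6-count library
    t_floor = max(tf.at_zero(), 1.5)
    t_ceil = 16.0
    total = 1_000_000.0
    t_lo = np.where(c > 0, t_floor, t_ceil)  # readout-minimizing config
    t_hi = np.where(c > 0, t_ceil, t_floor)  # readout-maximizing config
    lo = clock.intercept + float(c @ t_lo)
    hi = clock.intercept + float(c @ t_hi)
    if (ages < lo).any() or (ages > hi).any():
        raise GerosigError(
            f"ages outside the representable range [{lo:.1f}, {hi:.1f}] "
            "for this clock")
    lam = (ages - lo) / (hi - lo)
    t = np.outer(t_lo, 1.0 - lam) + np.outer(t_hi, lam)  # genes x samples
    f = tf.log_base ** t - tf.pseudocount
    if f.sum(axis=0).max() >= 0.9 * total:
        raise GerosigError("clock genes would dominate the library")
    counts = f  # 1 kb lengths + 1e6 library size make FPKM == counts
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        counts = np.clip(counts + rng.normal(0.0, noise_sd, counts.shape),
                         0.0, None)
    if sample_names is None:
        sample_names = [f"S{i:02d}" for i in range(1, len(ages) + 1)]
    gene_index = [g.capitalize() for g in coef.index] if mouse_symbols \
        else list(coef.index)
    vals = pd.DataFrame(counts, index=pd.Index(gene_index),
                        columns=list(sample_names))
    filler = "Filler0" if mouse_symbols else "FILLER0"
    vals.loc[filler] = np.clip(total - f.sum(axis=0), 0.0, None)
    lengths = pd.Series(1000.0, index=vals.index)
    grp = pd.Series(list(groups), index=vals.columns) if groups is not None \
        else None
    return ExpressionMatrix(vals, lengths, "counts", grp)


# ---------------------------------------------------------------------------
# marker / ambient fixture
# ---------------------------------------------------------------------------

@dataclass
class MarkerFixture:
    """Planted single-cell hygiene fixture with known contaminants."""

    markers: pd.DataFrame  # cell_type, gene, rank, statistic
    counts: pd.DataFrame  # genes x cells
    expr_ranks: pd.Series  # gene -> dataset-wide expression rank
    degs: dict[str, list]  # cell type -> DEG list
    contaminants: dict[str, set]  # cell type -> planted ambient DEGs
    top_gene: str  # planted most highly expressed gene


def simulate_marker_fixture(
    n_celltypes: int = 3,
    n_genes: int = 120,
    seed: int = 0,
    n_markers: int = 8,
    n_cells: int = 40,
) -> MarkerFixture:
    """Build marker lists, counts and DEG lists with planted contaminants.

    Each cell type's DEG list contains two planted contaminants — rank-1/2
    markers of the next cell type that are also within the top-50 expressed
    genes — alongside own markers, two near-misses that satisfy exactly one
    exclusion criterion each, and clean lowly expressed genes.  Counts are
    uniform across cells so the expression ranking is exactly the planted
    total order; three rare genes failing the expression prefilter are
    appended.
    """
    if n_celltypes < 2:
        raise GerosigError("need at least 2 cell types")
    need = n_celltypes * n_markers + 50 + 2 * n_celltypes
    if n_genes < need:
        raise GerosigError(f"need at least {need} genes")
    rng = np.random.default_rng(seed)
    genes = [f"M{i:04d}" for i in range(1, n_genes + 1)]
    celltypes = [f"CT{i:02d}" for i in range(1, n_celltypes + 1)]
    marker_rows = []
    marker_of: dict[str, list] = {}
    for i, ct in enumerate(celltypes):
        block = genes[i * n_markers:(i + 1) * n_markers]
        marker_of[ct] = block
        for rank, g in enumerate(block, start=1):
            marker_rows.append((ct, g, rank, float(n_markers - rank + 1)))
    markers = pd.DataFrame(marker_rows, columns=list(ambient.MARKER_COLUMNS))
    pool = genes[n_celltypes * n_markers:]
    top_gene = pool[0]
    # planted expression order: the top-50 block is exactly the top gene,
    # the rank-1/2 markers of every cell type, and housekeeping fill;
    # everything else (including rank-3+ markers) sits strictly below
    ordered = [top_gene]
    for ct in celltypes:
        ordered += marker_of[ct][:2]
    housekeeping = [g for g in pool[1:] if g not in ordered]
    n_fill = 50 - len(ordered)
    ordered += housekeeping[:n_fill]
    low_pool = housekeeping[n_fill:]
    ordered += [g for g in genes if g not in ordered]
    weights = {g: float(2 * (len(genes) - pos) + 2)
               for pos, g in enumerate(ordered)}
    counts = pd.DataFrame(
        {f"C{j:03d}": [weights[g] for g in genes] for j in range(1, n_cells + 1)},
        index=pd.Index(genes))
    # plus a few rare genes that fail the expression prefilter
    for r in range(1, 4):
        row = pd.Series(0.0, index=counts.columns, name=f"RARE{r:02d}")
        row.iloc[r] = 1.0
        counts.loc[row.name] = row
    expr_ranks = ambient.rank_expression(counts)
    degs: dict[str, list] = {}
    contaminants: dict[str, set] = {}
    low_iter = iter(low_pool)
    for i, ct in enumerate(celltypes):
        nxt = celltypes[(i + 1) % n_celltypes]
        planted = marker_of[nxt][:2]  # top markers of another type, top-50
        near_marker = marker_of[nxt][2]  # marker but lowly expressed
        near_expr = housekeeping[i]  # top-50 but nobody's marker
        clean = [next(low_iter), next(low_iter)]
        degs[ct] = marker_of[ct][:3] + planted + [near_marker, near_expr] + clean
        contaminants[ct] = set(planted)
    return MarkerFixture(markers, counts, expr_ranks, degs, contaminants,
                         top_gene)


# ---------------------------------------------------------------------------
# dataset writer
# ---------------------------------------------------------------------------

def _safe(label: str) -> str:
    return label.replace("|", "__").replace("/", "-")


def write_dataset(
    outdir: str | Path,
    seed: int = 0,
    n_genes: int = 1000,
    n_program: int = 100,
    noise_sd: float = 0.2,
    effect_sd: float = 1.0,
    contexts: Sequence[ContextKey] | None = None,
    n_sets: int = 30,
    set_size: int = 40,
    planted_frac: float = 0.5,
    clock_ages: Mapping[str, float] = None,
    clock_n_per_group: int = 5,
    clock_noise_sd: float = 0.5,
) -> GroundTruth:
    """Emit a complete synthetic dataset to ``outdir``.

    Writes signature tables + manifest, a GMT library, the signed aging
    reference list, the marker/counts fixture, a synthetic clock with
    mouse-symbol expression panels (geroprotective group planted 10 years
    younger than old controls), and ``truth.json`` recording the planted
    structure for downstream evaluation.
    """
    outdir = Path(outdir)
    (outdir / "signatures").mkdir(parents=True, exist_ok=True)
    truth = generate_ground_truth(n_genes, n_program, effect_sd, seed,
                                  noise_sd)
    if contexts is None:
        contexts = default_contexts()
    entries = []
    for ctx in contexts:
        table = simulate_signature(truth, ctx)
        rel = Path("signatures") / f"{_safe(ctx.label)}.tsv"
        write_signature_table(table, outdir / rel)
        entries.append((ctx, rel))
    write_manifest(entries, outdir / "manifest.tsv")
    # keep planted draws within the per-direction program pools when the
    # program is small
    set_size = min(set_size, max(10, (2 * n_program) // 5))
    library = simulate_gene_sets(truth, n_sets, set_size, planted_frac)
    write_gmt(library, outdir / "genesets.gmt")
    write_gene_list(truth.aging_reference(), outdir / "aging_genes.tsv")

    fixture = simulate_marker_fixture(seed=seed)
    ambient.write_marker_table(fixture.markers, outdir / "markers.tsv")
    ambient.write_counts(fixture.counts, outdir / "sc_counts.tsv")
    deg_rows = [(ct, g) for ct in sorted(fixture.degs)
                for g in fixture.degs[ct]]
    pd.DataFrame(deg_rows, columns=["cell_type", "gene"]).to_csv(
        outdir / "sc_degs.tsv", sep="\t", index=False)

    clock = make_test_clock(seed=seed)
    truth.clock = clock
    write_clock_model(clock, outdir / "clock_model.tsv")
    if clock_ages is None:
        clock_ages = {"old_control": 70.0, "gi_treated": 60.0, "young": 30.0}
    ages, groups = [], []
    for grp, age in clock_ages.items():
        ages += [age] * clock_n_per_group
        groups += [grp] * clock_n_per_group
    expr = simulate_clock_expression(clock, ages, noise_sd=clock_noise_sd,
                                     seed=seed + 1, groups=groups,
                                     mouse_symbols=True)
    expr.values.to_csv(outdir / "clock_expression.tsv", sep="\t")
    expr.lengths.rename("length").to_csv(outdir / "gene_lengths.tsv", sep="\t")
    pd.DataFrame({"sample": expr.values.columns, "group": groups}).to_csv(
        outdir / "clock_samples.tsv", sep="\t", index=False)
    clock_homolog_map(clock).to_csv(outdir / "homolog_map.tsv", sep="\t",
                                    index=False)

    truth_record = {
        "seed": seed,
        "program_genes": {g: float(e) for g, e in truth.effects.items()},
        "planted_sets": {sid: {"direction": ps.direction,
                               "members": sorted(ps.members)}
                         for sid, ps in truth.planted_sets.items()},
        "contaminants": {ct: sorted(v)
                         for ct, v in fixture.contaminants.items()},
        "clock_true_ages": {s: float(a)
                            for s, a in zip(expr.values.columns, ages)},
    }
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth_record, fh, indent=1, sort_keys=True)
    return truth
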