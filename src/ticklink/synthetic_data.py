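"""Synthetic tick-gut metagenome generator with planted ground truth.

Emulates the study design the pipeline targets: one pooled gut sample
per tick species and sex, annotated read-by-read with a bacterial genus
(full six-rank lineage) and an EC-style enzyme identifier.  Every
downstream stage has a recoverable planted truth:

* per-sample read counts are multinomial draws from a species-specific
  genus abundance vector; a chosen set of genera carries a sex effect
  (abundance multiplied by ``fold_change`` in one sex, renormalized);
* the genus x enzyme incidence (repertoire) realizes a configured
  redundancy spectrum over the bins {1, 2-4, 5-10, >=11} exactly
  (largest-remainder rounding), so the linkage stage's spectrum is
  known in advance;
* alignment-quality fields (e-value, identity, alignment length) are
  drawn from pass/fail mixtures so the annotation filters remove a
  known expected fraction of records;
* optional FASTQ output plants exact numbers of low-quality reads and
  artificial replicates so QC removals are known counts.

All randomness flows from a single seeded generator per call.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .linkage import DEFAULT_BINS, bin_label
from .profile_io import COLUMNS
from .read_qc import QCParams

_SPECIES_NAMES = ["AV", "IO", "IP"]  # A. variegatum, I. ovatus, I. persulcatus


def _default_spectrum_targets() -> dict:
    # 12% single-genus and 27% five-to-ten-genus enzymes; the remainder
    # split so that very widespread (>= 11 genera) enzymes stay rare.
    return {"1": 0.12, "2-4": 0.55, "5-10": 0.27, "11+": 0.06}


@dataclass(frozen=True)
class NoiseModel:
    """Pass/fail mixtures for the annotation-quality fields.

    A record drawn from the *fail* population violates all three
    annotation thresholds (e-value above 1e-5, identity below 60%,
    alignment shorter than 15 bp), so the fraction of records removed by
    the filters converges to ``p_fail``.  ``p_nonbacterial`` labels a
    record's lineage as non-bacterial contamination (removed by the
    domain filter, tallied independently of ``p_fail``).
    """

    p_fail: float = 0.1
    pass_log10_evalue: tuple = (-30.0, -6.0)
    pass_identity: tuple = (85.0, 100.0)
    pass_aln_len: tuple = (30, 120)
    fail_log10_evalue: tuple = (-4.0, -1.0)
    fail_identity: tuple = (30.0, 55.0)
    fail_aln_len: tuple = (5, 14)
    p_nonbacterial: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p_fail", "p_nonbacterial"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def all_pass(cls) -> "NoiseModel":
        """Noiseless setting: every record passes every filter."""
        return cls(p_fail=0.0, p_nonbacterial=0.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic generator.

    Defaults emulate the targeted design: 3 tick species x 2 sexes with
    one pooled sample each, 40 bacterial genera under >= 2 phyla, 100
    EC-style enzymes with a planted redundancy spectrum, 4 genera given
    an 8-fold sex effect, and 20,000 annotated reads per sample.
    """

    n_species: int = 3
    sexes: tuple = ("f", "m")
    n_genera: int = 40
    n_enzymes: int = 100
    spectrum_targets: dict = field(default_factory=_default_spectrum_targets)
    n_diff_genera: int = 4
    fold_change: float = 8.0
    reads_per_sample: int = 20000
    p_unannotated_function: float = 0.1
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        tot = sum(self.spectrum_targets.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"spectrum_targets must sum to 1, got {tot}")
        if any(v < 0 for v in self.spectrum_targets.values()):
            raise ValueError("spectrum_targets proportions must be >= 0")
        if self.n_diff_genera > self.n_genera:
            raise ValueError("n_diff_genera must be <= n_genera")
        if not (self.fold_change > 0):
            raise ValueError("fold_change must be > 0")
        if not (0 <= self.p_unannotated_function <= 1):
            raise ValueError("p_unannotated_function must be in [0, 1]")
        if self.n_species < 1 or self.n_genera < 1 or self.n_enzymes < 1:
            raise ValueError("counts must be positive")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def bins(self) -> tuple:
        return tuple(
            _parse_bin_label(lbl) for lbl in self.spectrum_targets
        )


def _parse_bin_label(lbl: str) -> tuple:
    if lbl.endswith("+"):
        return (int(lbl[:-1]), None)
    if "-" in lbl:
        lo, hi = lbl.split("-")
        return (int(lo), int(hi))
    return (int(lbl), int(lbl))


def largest_remainder(targets: dict, n: int) -> dict:
    """Integer allocation of n items by the largest-remainder method."""
    raw = {k: v * n for k, v in targets.items()}
    alloc = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(alloc.values())
    remainders = sorted(raw, key=lambda k: (-(raw[k] - alloc[k]), list(raw).index(k)))
    for k in remainders[:short]:
        alloc[k] += 1
    return alloc


@dataclass
class SampleSpec:
    sample_id: str
    species: str
    sex: str
    depth: int


@dataclass
class GroundTruth:
    """The generator's planted parameters, used by recovery tests."""

    genus_catalog: pd.DataFrame      # index genus, columns domain..family
    enzyme_catalog: list
    repertoire: pd.DataFrame         # genera x enzymes boolean incidence
    base_abundance: dict             # species -> pd.Series over genera (sums to 1)
    affected_genera: dict            # genus -> sex in which it is enriched
    expected_spectrum: pd.Series     # enzyme -> number of genera harboring it
    sample_plan: list                # list[SampleSpec]
    config: GeneratorConfig

    def __post_init__(self) -> None:
        for sp, vec in self.base_abundance.items():
            if abs(float(vec.sum()) - 1.0) > 1e-9:
                raise ValueError(f"abundance vector for {sp} does not sum to 1")
        if not np.array_equal(
            self.expected_spectrum.to_numpy(),
            self.repertoire.sum(axis=0).reindex(self.expected_spectrum.index).to_numpy(),
        ):
            raise ValueError("expected_spectrum must equal repertoire column sums")
        unknown = set(self.affected_genera) - set(self.genus_catalog.index)
        if unknown:
            raise ValueError(f"affected genera not in catalog: {sorted(unknown)}")

    def to_json(self, path) -> None:
        payload = {
            "seed": self.config.seed,
            "config": dataclasses.asdict(self.config),
            "genus_catalog": self.genus_catalog.reset_index().to_dict(orient="records"),
            "enzyme_catalog": list(self.enzyme_catalog),
            "repertoire": {
                g: [e for e in self.repertoire.columns if self.repertoire.loc[g, e]]
                for g in self.repertoire.index
            },
            "base_abundance": {
                sp: {g: float(v) for g, v in vec.items()}
                for sp, vec in self.base_abundance.items()
            },
            "affected_genera": dict(self.affected_genera),
            "expected_spectrum": {e: int(v) for e, v in self.expected_spectrum.items()},
            "sample_plan": [dataclasses.asdict(s) for s in self.sample_plan],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _make_lineage(n_genera: int) -> pd.DataFrame:
    """Nested synthetic lineage: 12 families / 6 orders / 3 classes / 3 phyla."""
    rows = []
    for g in range(n_genera):
        fam = g % 12
        order = fam // 2
        cls = order // 2
        phylum = cls
        rows.append(
            {
                "genus": f"Genus{g + 1:03d}",
                "domain": "Bacteria",
                "phylum": f"Phylum{phylum + 1}",
                "class": f"Class{cls + 1}",
                "order": f"Order{order + 1}",
                "family": f"Family{fam + 1}",
            }
        )
    return pd.DataFrame(rows).set_index("genus")


def _make_enzyme_ids(n: int) -> list:
    """Distinct EC-dot-notation identifiers (synthetic)."""
    ids = []
    i = 0
    while len(ids) < n:
        a = i % 6 + 1
        b = (i // 6) % 9 + 1
        c = (i // 54) % 9 + 1
        d = i // 486 + 1
        ids.append(f"{a}.{b}.{c}.{d}")
        i += 1
    return ids


def build_ground_truth(config: GeneratorConfig) -> GroundTruth:
    """Realize the planted community and repertoire for *config*.

    The repertoire realizes ``spectrum_targets`` exactly when
    ``n_enzymes * proportion`` is integral, else by largest-remainder
    rounding; deterministic for a fixed seed.  Raises "infeasible
    spectrum" when a positive-mass bin needs more genera than exist.
    """
    bins = config.bins
    for (lo, _hi), lbl in zip(bins, config.spectrum_targets):
        if config.spectrum_targets[lbl] > 0 and lo > config.n_genera:
            raise ValueError(
                f"infeasible spectrum: bin {lbl} needs >= {lo} genera, "
                f"only {config.n_genera} available"
            )
    rng = np.random.default_rng(config.seed)
    catalog = _make_lineage(config.n_genera)
    genera = list(catalog.index)
    enzymes = _make_enzyme_ids(config.n_enzymes)

    alloc = largest_remainder(config.spectrum_targets, config.n_enzymes)
    # target genus count per enzyme, drawn within its bin
    genus_counts = []
    for (lo, hi), lbl in zip(bins, config.spectrum_targets):
        k = alloc[lbl]
        if k == 0:
            continue
        cap = config.n_genera if hi is None else min(hi, config.n_genera)
        cap_hi = min(cap, config.n_genera, lo + 4 if hi is None else cap)
        genus_counts.extend(rng.integers(lo, cap_hi + 1, size=k).tolist())
    order = rng.permutation(len(genus_counts))
    genus_counts = [genus_counts[i] for i in order]

    # assign genera per enzyme; prefer still-empty genera so that every
    # genus harbors at least one enzyme whenever slots suffice
    incidence = np.zeros((config.n_genera, config.n_enzymes), dtype=bool)
    empty = list(rng.permutation(config.n_genera))
    for j, k in enumerate(genus_counts):
        chosen: list[int] = []
        while empty and len(chosen) < k:
            chosen.append(empty.pop())
        if len(chosen) < k:
            pool = np.setdiff1d(np.arange(config.n_genera), np.asarray(chosen, dtype=int))
            extra = rng.choice(pool, size=k - len(chosen), replace=False)
            chosen.extend(int(e) for e in extra)
        incidence[chosen, j] = True
    repertoire = pd.DataFrame(incidence, index=genera, columns=enzymes)

    base_abundance = {}
    species = [_SPECIES_NAMES[i] if i < len(_SPECIES_NAMES) else f"SP{i + 1}"
               for i in range(config.n_species)]
    for sp in species:
        w = rng.lognormal(mean=0.0, sigma=1.5, size=config.n_genera)
        base_abundance[sp] = pd.Series(w / w.sum(), index=genera)

    # sex-affected genera drawn from the more abundant half so the planted
    # effect is observable at the configured depth; direction alternates
    mean_ab = sum(base_abundance[sp] for sp in species) / len(species)
    ranked = mean_ab.sort_values(ascending=False)
    candidates = list(ranked.index[: max(config.n_diff_genera, config.n_genera // 2)])
    picked = rng.choice(len(candidates), size=config.n_diff_genera, replace=False)
    affected = {
        candidates[int(i)]: config.sexes[j % len(config.sexes)]
        for j, i in enumerate(sorted(picked))
    }

    plan = []
    for sp in species:
        for sex in config.sexes:
            for rep in range(config.n_replicates):
                sid = f"{sp}{sex}" + (f"_{rep + 1}" if config.n_replicates > 1 else "")
                plan.append(SampleSpec(sid, sp, sex, config.reads_per_sample))

    return GroundTruth(
        genus_catalog=catalog,
        enzyme_catalog=enzymes,
        repertoire=repertoire,
        base_abundance=base_abundance,
        affected_genera=affected,
        expected_spectrum=repertoire.sum(axis=0),
        sample_plan=plan,
        config=config,
    )


def sample_genus_probabilities(truth: GroundTruth, species: str, sex: str) -> pd.Series:
    """Per-genus sampling probabilities for one sample (effect applied)."""
    p = truth.base_abundance[species].copy()
    for genus, enriched_sex in truth.affected_genera.items():
        if sex == enriched_sex:
            p[genus] *= truth.config.fold_change
    return p / p.sum()


def simulate_annotation_tables(truth: GroundTruth):
    """Draw the per-read annotation table and sample metadata.

    For each planned sample, reads are multinomial draws from the
    species' genus vector with the sex effect applied; each read gets an
    enzyme drawn uniformly from its genus' repertoire with probability
    1 - p_unannotated_function, else a missing function; quality fields
    come from the configured pass/fail mixtures.  Returns
    ``(annotation_table, metadata)`` DataFrames.
    """
    cfg = truth.config
    noise = cfg.noise
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1,)))
    genera = list(truth.genus_catalog.index)
    enzyme_lists = {
        g: np.asarray(
            [e for e in truth.repertoire.columns if truth.repertoire.loc[g, e]],
            dtype=object,
        )
        for g in genera
    }
    lineage = truth.genus_catalog  # index genus

    frames = []
    for spec in truth.sample_plan:
        if spec.depth <= 0:
            raise ValueError(f"sample {spec.sample_id}: depth must be positive")
        probs = sample_genus_probabilities(truth, spec.species, spec.sex)
        counts = rng.multinomial(spec.depth, probs.to_numpy())
        genus_idx = np.repeat(np.arange(len(genera)), counts)
        n = genus_idx.size

        # enzyme assignment, vectorized per genus
        enzyme = np.full(n, None, dtype=object)
        need_fun = rng.random(n) >= cfg.p_unannotated_function
        for gi in np.nonzero(counts)[0]:
            sel = np.nonzero((genus_idx == gi) & need_fun)[0]
            if sel.size == 0:
                continue
            pool = enzyme_lists[genera[gi]]
            if pool.size == 0:
                raise ValueError(
                    f"empty repertoire row for genus {genera[gi]} with function requested"
                )
            enzyme[sel] = pool[rng.integers(0, pool.size, size=sel.size)]

        fail = rng.random(n) < noise.p_fail
        log10e = np.where(
            fail,
            rng.uniform(*noise.fail_log10_evalue, size=n),
            rng.uniform(*noise.pass_log10_evalue, size=n),
        )
        identity = np.where(
            fail,
            rng.uniform(*noise.fail_identity, size=n),
            rng.uniform(*noise.pass_identity, size=n),
        )
        aln = np.where(
            fail,
            rng.integers(noise.fail_aln_len[0], noise.fail_aln_len[1] + 1, size=n),
            rng.integers(noise.pass_aln_len[0], noise.pass_aln_len[1] + 1, size=n),
        )
        nonbact = rng.random(n) < noise.p_nonbacterial

        genus_names = np.asarray(genera, dtype=object)[genus_idx]
        df = pd.DataFrame(
            {
                "feature_id": [f"{spec.sample_id}_r{i:06d}" for i in range(n)],
                "sample_id": spec.sample_id,
                "hits": 1,
                "evalue": np.power(10.0, log10e),
                "identity_pct": identity,
                "aln_len": aln.astype(np.int64),
                "genus": genus_names,
            }
        )
        for rank in ("domain", "phylum", "class", "order", "family"):
            df[rank] = lineage[rank].reindex(genus_names).to_numpy()
        # non-bacterial contamination: eukaryote domain, lineage unresolved below
        if nonbact.any():
            df.loc[nonbact, "domain"] = "Eukaryota"
            for rank in ("phylum", "class", "order", "family", "genus"):
                df.loc[nonbact, rank] = None
        ez = pd.Series(enzyme, dtype=object)
        df["func_l4"] = ez
        has_fun = ez.notna()
        df["func_l1"] = ez.where(~has_fun, "L1_" + ez.str.split(".").str[0])
        df["func_l2"] = ez.where(
            ~has_fun, "L2_" + ez.str.split(".").str[:2].str.join(".")
        )
        df["func_l3"] = ez.where(
            ~has_fun, "L3_" + ez.str.split(".").str[:3].str.join(".")
        )
        df["subject_id"] = [f"M5_{v:08d}" for v in rng.integers(0, 10**8, size=n)]
        frames.append(df)

    table = pd.concat(frames, ignore_index=True)[COLUMNS]
    table["hits"] = table["hits"].astype(np.int64)
    metadata = pd.DataFrame(
        [(s.sample_id, s.species, s.sex) for s in truth.sample_plan],
        columns=["sample_id", "species", "sex"],
    )
    return table, metadata


# ---------------------------------------------------------------------------
# FASTQ simulation with planted QC removals


@dataclass(frozen=True)
class ReadSimPlan:
    """Planted composition of one sample's simulated FASTQ.

    ``low_quality`` reads are built so that every window of the QC
    minimum length exceeds the below-floor budget (hence removed by the
    quality filter); ``duplicates`` reads copy the prefix of an earlier
    read (hence removed by dereplication).
    """

    n_reads: int = 100
    read_len: int = 150
    low_quality: int = 0
    duplicates: int = 0
    gc_mean: float = 0.5

    def __post_init__(self) -> None:
        if self.low_quality + self.duplicates > self.n_reads:
            raise ValueError("planted counts exceed total reads")
        if not (0 < self.gc_mean < 1):
            raise ValueError("gc_mean must be in (0, 1)")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")


def _random_seq(rng, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.asarray(list("AGCT"), dtype=object)[rng.choice(4, size=length, p=p)])


def simulate_reads(
    truth: GroundTruth, qc_plan, params: QCParams | None = None
) -> dict:
    """Simulate FASTQ read sets with planted QC removals.

    *qc_plan* maps sample ids to :class:`ReadSimPlan` (a single plan is
    broadcast to every planned sample).  Returns a dict sample id ->
    list of ``SeqRecord`` (Phred+33 qualities).  Good reads have all
    qualities at or above the floor and pairwise-distinct prefixes;
    planted low-quality reads have every base below the floor; planted
    duplicates copy the prefix of an earlier good read at equal length,
    so quality filtering then dereplication remove exactly the planted
    counts.
    """
    params = params or QCParams()
    if isinstance(qc_plan, ReadSimPlan):
        qc_plan = {s.sample_id: qc_plan for s in truth.sample_plan}
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=truth.config.seed, spawn_key=(2,))
    )
    out = {}
    for sample_id, plan in qc_plan.items():
        if plan.duplicates > 0 and plan.read_len < params.dup_prefix_len:
            raise ValueError("requested read length < duplicate-prefix length")
        if plan.read_len < params.min_len:
            raise ValueError("read length below QC min_len: good reads would be removed")
        if params.min_len <= params.max_below:
            raise ValueError("min_len must exceed max_below for planted removals")
        n_good = plan.n_reads - plan.low_quality - plan.duplicates
        if plan.duplicates > 0 and n_good < 1:
            raise ValueError("duplicates require at least one good source read")
        seen_prefixes: set[str] = set()
        records = []

        def _fresh_seq() -> str:
            while True:
                seq = _random_seq(rng, plan.read_len, plan.gc_mean)
                if seq[: params.dup_prefix_len] not in seen_prefixes:
                    seen_prefixes.add(seq[: params.dup_prefix_len])
                    return seq

        goods = []
        for i in range(n_good):
            seq = _fresh_seq()
            quals = rng.integers(params.phred_floor, 41, size=plan.read_len).tolist()
            rec = SeqRecord(Seq(seq), id=f"{sample_id}_read{len(records):05d}",
                            description="")
            rec.letter_annotations["phred_quality"] = quals
            records.append(rec)
            goods.append(seq)
        for i in range(plan.duplicates):
            src = goods[int(rng.integers(0, len(goods)))]
            tail_len = plan.read_len - params.dup_prefix_len
            seq = src[: params.dup_prefix_len] + _random_seq(rng, tail_len, plan.gc_mean)
            quals = rng.integers(params.phred_floor, 41, size=plan.read_len).tolist()
            rec = SeqRecord(Seq(seq), id=f"{sample_id}_read{len(records):05d}",
                            description="")
            rec.letter_annotations["phred_quality"] = quals
            records.append(rec)
        low_q = max(params.phred_floor - 1, 0)
        for i in range(plan.low_quality):
            seq = _fresh_seq()
            rec = SeqRecord(Seq(seq), id=f"{sample_id}_read{len(records):05d}",
                            description="")
            rec.letter_annotations["phred_quality"] = [low_q] * plan.read_len
            records.append(rec)
        out[sample_id] = records
    return out
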