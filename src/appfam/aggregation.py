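"""Amyloid-aggregation potential modelling.

Two complementary signals are combined, mirroring how cross-β aggregation
is usually called on a protein sequence:

* a **β-pairing energy profile**: every pair of equal-length ungapped
  windows of the sequence (both parallel and antiparallel orientation,
  self-pairing allowed with register shift >= 1) is scored by summing
  tabulated residue-pair energies; each residue's profile value is the
  minimum (most stabilising) energy among pairings covering it.  Energies
  below −4 mark regions compatible with ordered β-fibrils, −4..−3 marginal,
  above −2 non-amyloidogenic.
* a **k-of-n consensus predictor**: independent sliding-window scorers
  (hydrophobicity, β-sheet propensity, an amyloid-prone hexapeptide
  stretch detector) each flag residues; a residue reaches consensus when
  at least ``k`` scorers agree (default k=2).

Segments require both signals (energy band AND consensus).  A per-taxon
call then follows the two-region rule: a stable amyloid β-fold needs
qualifying segments in *both* the N-terminal and C-terminal windows of the
βA4-homologous region; the N-terminal segment's band sets the class.

The packaged pairing-energy table is a synthetic surrogate (see
``surrogate_energy_table``): an affinely calibrated outer product of a
β-aggregation propensity scale, signed so hydrophobic/β-prone pairs are
stabilising.  It reproduces the qualitative behaviour of published
β-pairing potentials (hydrophobic stretches score deeply negative,
polar/charged sequence scores positive) but not their numeric values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.ndimage import minimum_filter1d

from .trees import PhyloTree
from .types import AA_ALPHABET, AlignedMatrix, DomainMap

log = logging.getLogger(__name__)

NO_PAIRING = math.inf  #: sentinel profile value for uncoverable residues

#: classification thresholds: high < HIGH_T; LOW_T <= low <= HIGH_T band
HIGH_THRESHOLD = -4.0
LOW_THRESHOLD = -3.0
STOP_THRESHOLD = -2.0

#: β-aggregation propensity, 0 (never aggregates) .. 1 (strongly prone)
BETA_PROPENSITY = {
    "I": 1.00, "V": 0.95, "F": 0.90, "L": 0.85, "M": 0.70, "W": 0.65,
    "Y": 0.60, "C": 0.55, "A": 0.50, "T": 0.35, "H": 0.30, "G": 0.25,
    "Q": 0.25, "S": 0.20, "N": 0.20, "K": 0.10, "R": 0.10, "E": 0.05,
    "D": 0.05, "P": 0.00,
}

# surrogate calibration constants (see surrogate_energy_table)
_GAMMA = 1.1
_THETA = 0.25
_ANTI_FACTOR = 1.05

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Chou–Fasman-style β-sheet conformational preferences
CHOU_FASMAN_BETA = {
    "V": 1.70, "I": 1.60, "Y": 1.47, "F": 1.38, "W": 1.37, "L": 1.30,
    "C": 1.19, "T": 1.19, "Q": 1.10, "M": 1.05, "R": 0.93, "N": 0.89,
    "H": 0.87, "A": 0.83, "S": 0.75, "G": 0.75, "K": 0.74, "P": 0.55,
    "D": 0.54, "E": 0.37,
}

#: residues tolerated inside an amyloid-prone hexapeptide stretch
AMYLOID_PRONE_SET = frozenset("IVLFMWYCAT")


# ----------------------------------------------------------------------
# pairing energy table
# ----------------------------------------------------------------------

@dataclass
class PairingEnergyTable:
    """20×20 residue-pair energies, one matrix per strand orientation."""

    parallel: np.ndarray
    antiparallel: np.ndarray
    alphabet: str = AA_ALPHABET
    provenance: str = "unspecified"

    def __post_init__(self):
        n = len(self.alphabet)
        for name in ("parallel", "antiparallel"):
            m = getattr(self, name)
            if m.shape != (n, n):
                raise ValueError(f"{name} matrix must be {n}×{n}")
            if not np.isfinite(m).all():
                raise ValueError(f"{name} matrix has non-finite entries")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} matrix must be symmetric")

    def matrix(self, orientation: str) -> np.ndarray:
        if orientation == "parallel":
            return self.parallel
        if orientation == "antiparallel":
            return self.antiparallel
        raise ValueError(f"unknown orientation {orientation!r}")

    def pair_energy(self, a: str, b: str, orientation: str) -> float:
        idx = {c: i for i, c in enumerate(self.alphabet)}
        if a not in idx or b not in idx:
            return 0.0  # unknown residues are energetically neutral
        return float(self.matrix(orientation)[idx[a], idx[b]])

    # -- serialization --------------------------------------------------
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#provenance={self.provenance}\n")
            for name in ("parallel", "antiparallel"):
                m = getattr(self, name)
                fh.write(f"#matrix={name}\n")
                fh.write("\t" + "\t".join(self.alphabet) + "\n")
                for i, row_letter in enumerate(self.alphabet):
                    vals = "\t".join(f"{m[i, j]:.8f}"
                                     for j in range(len(self.alphabet)))
                    fh.write(f"{row_letter}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path) -> "PairingEnergyTable":
        matrices: dict[str, list[list[float]]] = {}
        provenance = "unspecified"
        current: list[list[float]] | None = None
        alphabet: str | None = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                if line.startswith("#provenance="):
                    provenance = line.split("=", 1)[1]
                elif line.startswith("#matrix="):
                    current = []
                    matrices[line.split("=", 1)[1]] = current
                elif line.startswith("\t"):
                    alphabet = "".join(line.strip().split("\t"))
                else:
                    fields = line.split("\t")
                    current.append([float(x) for x in fields[1:]])
        return cls(parallel=np.array(matrices["parallel"]),
                   antiparallel=np.array(matrices["antiparallel"]),
                   alphabet=alphabet or AA_ALPHABET,
                   provenance=provenance)


def surrogate_energy_table() -> PairingEnergyTable:
    """Synthetic β-pairing energies from a propensity outer product.

    ``E(a, b) = -γ (p_a p_b - θ)`` per paired position, with antiparallel
    pairings scaled slightly stronger.  The constants are calibrated once
    so that (i) the C-terminal half of human Aβ42 profiles below −4,
    (ii) a poly-serine control stays above −2, and (iii) planted
    hydrophobic 8-mers in polar background yield qualifying segments.
    """
    p = np.array([BETA_PROPENSITY[c] for c in AA_ALPHABET])
    par = -_GAMMA * (np.outer(p, p) - _THETA)
    return PairingEnergyTable(parallel=par,
                              antiparallel=_ANTI_FACTOR * par,
                              provenance="synthetic-surrogate "
                              f"(gamma={_GAMMA}, theta={_THETA}, "
                              f"anti={_ANTI_FACTOR})")


def default_energy_table() -> PairingEnergyTable:
    """The packaged surrogate table (read from package data if present)."""
    try:
        path = resources.files("appfam").joinpath(
            "data/pairing_energies_surrogate.tsv")
        with resources.as_file(path) as p:
            return PairingEnergyTable.from_tsv(p)
    except (FileNotFoundError, ModuleNotFoundError):
        return surrogate_energy_table()


# ----------------------------------------------------------------------
# energy profile
# ----------------------------------------------------------------------

@dataclass
class EnergyProfile:
    """Per-residue best (minimum) pairing energy and orientation."""

    sequence: str
    energies: np.ndarray      # NO_PAIRING where no admissible pairing
    orientation: np.ndarray   # "parallel" | "antiparallel" | "" per residue
    min_strand_len: int

    def __len__(self):
        return len(self.sequence)

    @property
    def min_energy(self) -> float:
        """Global minimum pairing energy (NO_PAIRING if none admissible)."""
        return float(self.energies.min()) if len(self.energies) else NO_PAIRING


def _orientation_profile(seq_idx: np.ndarray, mat: np.ndarray,
                         min_strand_len: int, antiparallel: bool,
                         max_strand_len: int | None = None) -> np.ndarray:
    """Per-residue minimum window-pair energy for one orientation.

    Works diagonal-by-diagonal on the residue-pair energy matrix: window
    sums come from cumulative sums, and the minimum over the windows
    covering each residue is a trailing sliding-window minimum.
    """
    L = len(seq_idx)
    E = mat[np.ix_(seq_idx, seq_idx)]
    prof = np.full(L, NO_PAIRING)
    lmin = min_strand_len

    if not antiparallel:
        for d in range(1, L - lmin + 1):
            v = np.diagonal(E, offset=d)      # v[t] = E[t, t+d]
            m = len(v)
            if m < lmin:
                continue
            cs = np.concatenate(([0.0], np.cumsum(v)))
            lmax = m if max_strand_len is None else min(m, max_strand_len)
            for ell in range(lmin, lmax + 1):
                W = cs[ell:] - cs[:-ell]      # sums of windows length ell
                cov = _cover_min(W, ell, m)
                np.minimum(prof[:m], cov, out=prof[:m])
                np.minimum(prof[d:d + m], cov, out=prof[d:d + m])
    else:
        for c in range(lmin - 1, 2 * L - lmin):
            t_lo = max(0, c - L + 1)
            t_hi = min(L - 1, c)
            m = t_hi - t_lo + 1
            if m < lmin:
                continue
            t = np.arange(t_lo, t_hi + 1)
            u = E[t, c - t]
            cs = np.concatenate(([0.0], np.cumsum(u)))
            lmax = m if max_strand_len is None else min(m, max_strand_len)
            for ell in range(lmin, lmax + 1):
                W = cs[ell:] - cs[:-ell]
                # exclude the identical-window hairpin: first window start
                # a (absolute) equals second start c - a - ell + 1
                twice_a = c - ell + 1
                if twice_a % 2 == 0:
                    a = twice_a // 2
                    k = a - t_lo
                    if 0 <= k < len(W):
                        W = W.copy()
                        W[k] = NO_PAIRING
                cov = _cover_min(W, ell, m)
                both = np.minimum(cov, cov[::-1])
                np.minimum(prof[t_lo:t_hi + 1], both,
                           out=prof[t_lo:t_hi + 1])
    return prof


def _cover_min(W: np.ndarray, ell: int, m: int) -> np.ndarray:
    """cov[r] = min of W over window starts t with t <= r <= t+ell-1."""
    Wp = np.full(m, NO_PAIRING)
    Wp[: len(W)] = W
    origin = (ell - 1) // 2  # scipy: positive origin shifts the window left
    return minimum_filter1d(Wp, size=ell, mode="constant",
                            cval=NO_PAIRING, origin=origin)


def pasta_energy_profile(seq: str, table: PairingEnergyTable | None = None,
                         min_strand_len: int = 4,
                         max_strand_len: int | None = None) -> EnergyProfile:
    """β-pairing energy profile of one sequence.

    Considers every pair of equal-length ungapped windows (length >=
    ``min_strand_len``; identical self-windows excluded, register-shifted
    self-pairings allowed) in both orientations; each residue receives the
    minimum total energy among pairings whose windows cover it.  Residues
    outside the 20-letter alphabet contribute zero energy (logged).
    """
    table = table or default_energy_table()
    idx_map = {c: i for i, c in enumerate(table.alphabet)}
    n = len(table.alphabet)
    unknown = sorted({c for c in seq if c not in idx_map})
    if unknown:
        log.info("residues %s scored as neutral (unknown to the energy "
                 "table)", unknown)
    # pad the matrices with a neutral row/column for unknown residues
    seq_idx = np.array([idx_map.get(c, n) for c in seq])
    L = len(seq)
    if L < 2 * min_strand_len:
        empty = np.full(L, NO_PAIRING)
        return EnergyProfile(seq, empty, np.full(L, "", dtype=object),
                             min_strand_len)
    profs = {}
    for name, anti in (("parallel", False), ("antiparallel", True)):
        mat = np.zeros((n + 1, n + 1))
        mat[:n, :n] = table.matrix(name)
        profs[name] = _orientation_profile(seq_idx, mat, min_strand_len,
                                           anti, max_strand_len)
    energies = np.minimum(profs["parallel"], profs["antiparallel"])
    orientation = np.where(
        energies == NO_PAIRING, "",
        np.where(profs["antiparallel"] <= profs["parallel"],
                 "antiparallel", "parallel")).astype(object)
    return EnergyProfile(seq, energies, orientation, min_strand_len)


def brute_force_profile(seq: str, table: PairingEnergyTable | None = None,
                        min_strand_len: int = 4,
                        max_strand_len: int | None = None) -> np.ndarray:
    """Exhaustive O(L⁴) reference implementation of the energy profile.

    Enumerates every window pair and orientation explicitly; intended for
    short sequences and cross-checks.
    """
    table = table or default_energy_table()
    L = len(seq)
    prof = np.full(L, NO_PAIRING)
    lmax_all = L if max_strand_len is None else max_strand_len
    for ell in range(min_strand_len, lmax_all + 1):
        for i in range(L - ell + 1):
            for j in range(L - ell + 1):
                if i == j:
                    continue
                e_par = sum(table.pair_energy(seq[i + k], seq[j + k],
                                              "parallel")
                            for k in range(ell))
                e_anti = sum(table.pair_energy(seq[i + k],
                                               seq[j + ell - 1 - k],
                                               "antiparallel")
                             for k in range(ell))
                e = min(e_par, e_anti)
                for k in range(ell):
                    for pos in (i + k, j + k):
                        if e < prof[pos]:
                            prof[pos] = e
    return prof


# ----------------------------------------------------------------------
# consensus predictor
# ----------------------------------------------------------------------

@dataclass
class WindowScorer:
    """Thresholded sliding-window scorer flagging residues."""

    name: str
    scale: dict[str, float]
    window: int
    threshold: float
    mode: str = "mean"  # "mean": centred window mean >= threshold
                        # "all_in_set": all window residues have scale > 0

    def flags(self, seq: str) -> np.ndarray:
        L = len(seq)
        vals = np.array([self.scale.get(c, 0.0) for c in seq])
        out = np.zeros(L, dtype=bool)
        if L == 0:
            return out
        if self.mode == "mean":
            half = self.window // 2
            for r in range(L):
                lo, hi = max(0, r - half), min(L, r + half + 1)
                out[r] = vals[lo:hi].mean() >= self.threshold
        elif self.mode == "all_in_set":
            for start in range(0, L - self.window + 1):
                if np.all(vals[start:start + self.window] > 0):
                    out[start:start + self.window] = True
        else:
            raise ValueError(f"unknown scorer mode {self.mode!r}")
        return out


def default_scorers() -> list[WindowScorer]:
    return [
        WindowScorer("hydrophobicity", KYTE_DOOLITTLE, window=5,
                     threshold=1.5),
        WindowScorer("beta_propensity", CHOU_FASMAN_BETA, window=5,
                     threshold=1.2),
        WindowScorer("hexapeptide_stretch",
                     {c: 1.0 for c in AMYLOID_PRONE_SET}, window=6,
                     threshold=1.0, mode="all_in_set"),
    ]


def consensus_predict(seq: str, scorers: list[WindowScorer] | None = None,
                      k: int = 2) -> np.ndarray:
    """Per-residue boolean: flagged by at least ``k`` scorers."""
    scorers = default_scorers() if scorers is None else scorers
    if k > len(scorers):
        raise ValueError(f"k={k} exceeds the {len(scorers)} scorers")
    votes = np.zeros(len(seq), dtype=int)
    for s in scorers:
        votes += s.flags(seq)
    return votes >= k


# ----------------------------------------------------------------------
# segment and taxon classification
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    start: int  # 0-based half-open
    end: int
    klass: str  # "high" | "low"
    min_energy: float


def classify_segments(profile: EnergyProfile, consensus: np.ndarray,
                      min_run: int = 3,
                      high_threshold: float = HIGH_THRESHOLD,
                      low_threshold: float = LOW_THRESHOLD) -> list[Segment]:
    """Maximal runs where the energy band and the consensus flag agree.

    high: energy < high_threshold AND consensus;
    low:  high_threshold <= energy <= low_threshold AND consensus.
    Runs shorter than ``min_run`` are dropped.
    """
    e = profile.energies
    if len(e) != len(consensus):
        raise ValueError("profile and consensus lengths differ")
    klass = np.full(len(e), "", dtype=object)
    klass[(e < high_threshold) & consensus] = "high"
    klass[(e >= high_threshold) & (e <= low_threshold) & consensus] = "low"
    segments = []
    start = 0
    for r in range(1, len(e) + 1):
        if r == len(e) or klass[r] != klass[start]:
            if klass[start] and (r - start) >= min_run:
                segments.append(Segment(
                    start, r, str(klass[start]),
                    float(e[start:r].min())))
            start = r
    return segments


def truncation_scan(seq: str, table: PairingEnergyTable | None = None,
                    min_strand_len: int = 4,
                    stop_threshold: float = STOP_THRESHOLD,
                    ) -> list[tuple[int, float]]:
    """Global minimum pairing energy under sequential C-terminal truncation.

    Evaluates the full sequence, then repeatedly drops the final residue,
    recording ``(remaining length, min energy)``, and stops the first time
    the energy rises above ``stop_threshold`` (that entry is included).
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    table = table or default_energy_table()
    out = []
    s = seq
    while s:
        e = pasta_energy_profile(s, table, min_strand_len).min_energy
        out.append((len(s), e))
        if e > stop_threshold:
            break
        s = s[:-1]
    return out


def classify_taxon(n_segments: list[Segment],
                   c_segments: list[Segment]) -> str:
    """Two-region rule: both windows must carry a qualifying segment; the
    best (lowest-energy class) N-terminal segment sets the call."""
    if not n_segments or not c_segments:
        return "none"
    n_best = "high" if any(s.klass == "high" for s in n_segments) else "low"
    return n_best


# ----------------------------------------------------------------------
# βA4-homologous region extraction
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CleavageSites:
    """β/α/γ-secretase cut positions, 0-based residue indices on the
    taxon's own (degapped) sequence; the region runs [beta, gamma)."""

    taxon_id: str
    beta: int
    alpha: int
    gamma: int

    def __post_init__(self):
        if not self.beta < self.alpha < self.gamma:
            raise ValueError(
                f"{self.taxon_id}: need beta < alpha < gamma, got "
                f"({self.beta}, {self.alpha}, {self.gamma})")


def read_cleavage_sites(path) -> dict[str, CleavageSites]:
    """TSV: taxon<TAB>beta<TAB>alpha<TAB>gamma (1-based start positions of
    the residue following each cut; on-disk convention documented in the
    packaged example)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            taxon, b, a, g = line.split("\t")[:4]
            out[taxon] = CleavageSites(taxon, int(b) - 1, int(a) - 1,
                                       int(g) - 1)
    return out


@dataclass(frozen=True)
class RegionExtract:
    taxon_id: str
    n_window: tuple[int, int]  # own-sequence coords, 0-based half-open
    c_window: tuple[int, int]
    n_seq: str
    c_seq: str
    full_seq: str
    provenance: str  # "own" | "neighbor:<taxon>" | "fallback-reference"


def _col_of_residue(row: str, k: int) -> int:
    seen = -1
    for j, c in enumerate(row):
        if c != "-":
            seen += 1
            if seen == k:
                return j
    raise ValueError(f"residue index {k} beyond row length {seen + 1}")


def _window_from_columns(row: str, c0: int, c1: int) -> tuple[int, int, str]:
    before = sum(1 for c in row[:c0] if c != "-")
    sub = row[c0:c1].replace("-", "")
    return before, before + len(sub), sub


def extract_ba4_regions(matrix: AlignedMatrix, domain_map: DomainMap,
                        cleavage: dict[str, CleavageSites],
                        tree: PhyloTree | None = None,
                        ) -> dict[str, RegionExtract]:
    """Per-taxon N-/C-terminal windows of the βA4-homologous region.

    Boundary columns come from (1) the taxon's own annotated cleavage
    sites, else (2) the nearest annotated taxon on the tree, else (3) the
    reference taxon's annotation projected through the alignment.  The
    region is split at the α-site column into the N-terminal and
    C-terminal windows.
    """
    ref_id = domain_map.reference_id
    if ref_id not in matrix.row_ids:
        raise KeyError(f"reference row {ref_id!r} missing from alignment")
    if ref_id not in cleavage:
        raise KeyError(f"reference taxon {ref_id!r} must carry cleavage "
                       "annotations")
    # sanity: βA4 must be declared in the map
    if not any("A4" in e.name or e.name.lower() in ("ba4", "abeta")
               for e in domain_map):
        log.warning("domain map has no βA4-like entry; proceeding on "
                    "cleavage annotations alone")

    dists = _tip_distances(tree) if tree is not None else {}
    annotated = sorted(cleavage)

    out: dict[str, RegionExtract] = {}
    for rid in matrix.row_ids:
        if rid in cleavage:
            src, provenance = rid, "own"
        else:
            neighbor = _nearest_annotated(rid, annotated, dists)
            if neighbor is not None:
                src, provenance = neighbor, f"neighbor:{neighbor}"
            else:
                src, provenance = ref_id, "fallback-reference"
        sites = cleavage[src]
        src_row = matrix.row(src)
        cb = _col_of_residue(src_row, sites.beta)
        ca = _col_of_residue(src_row, sites.alpha)
        cg = _col_of_residue(src_row, sites.gamma - 1) + 1
        row = matrix.row(rid)
        n0, n1, nseq = _window_from_columns(row, cb, ca)
        c0, c1, cseq = _window_from_columns(row, ca, cg)
        out[rid] = RegionExtract(
            taxon_id=rid, n_window=(n0, n1), c_window=(c0, c1),
            n_seq=nseq, c_seq=cseq, full_seq=nseq + cseq,
            provenance=provenance)
    return out


def _tip_distances(tree: PhyloTree) -> dict[tuple[str, str], int]:
    """Topological (edge-count) distances between all tip pairs."""
    tips = tree.tips()
    anc: dict[str, list] = {}
    for tip in tips:
        chain = []
        node = tip
        while node is not None:
            chain.append(id(node))
            node = node.parent
        anc[tip.label] = chain
    out = {}
    for i, a in enumerate(tips):
        ca = anc[a.label]
        depth_a = {nid: d for d, nid in enumerate(ca)}
        for b in tips[i + 1:]:
            for db, nid in enumerate(anc[b.label]):
                if nid in depth_a:
                    d = depth_a[nid] + db
                    break
            out[(a.label, b.label)] = d
            out[(b.label, a.label)] = d
    return out


def _nearest_annotated(rid: str, annotated: list[str],
                       dists: dict) -> str | None:
    candidates = [(dists[(rid, a)], a) for a in annotated
                  if (rid, a) in dists]
    if not candidates:
        return None
    return min(candidates)[1]


# ----------------------------------------------------------------------
# per-taxon calls on the tree
# ----------------------------------------------------------------------

@dataclass
class AmyloidCall:
    taxon_id: str
    klass: str  # "high" | "low" | "none"
    n_segments: list[Segment]
    c_segments: list[Segment]
    provenance: str = ""

    @property
    def has_n_segment(self) -> bool:
        return bool(self.n_segments)

    @property
    def has_c_segment(self) -> bool:
        return bool(self.c_segments)


def call_taxon(region: RegionExtract,
               table: PairingEnergyTable | None = None,
               scorers: list[WindowScorer] | None = None, k: int = 2,
               min_strand_len: int = 4, min_run: int = 3) -> AmyloidCall:
    """Energy + consensus over the full βA4-homologous region, segments
    split by window, then the two-region classification."""
    table = table or default_energy_table()
    seq = region.full_seq
    if not seq:
        return AmyloidCall(region.taxon_id, "none", [], [],
                           region.provenance)
    profile = pasta_energy_profile(seq, table, min_strand_len)
    cons = consensus_predict(seq, scorers, k=k)
    # energies use the whole region (the two strands stabilise each other);
    # segments are then classified within each window separately so a
    # single boundary-spanning run cannot satisfy the two-region rule
    n_len = len(region.n_seq)
    n_prof = EnergyProfile(seq[:n_len], profile.energies[:n_len],
                           profile.orientation[:n_len], min_strand_len)
    c_prof = EnergyProfile(seq[n_len:], profile.energies[n_len:],
                           profile.orientation[n_len:], min_strand_len)
    n_segs = classify_segments(n_prof, cons[:n_len], min_run=min_run)
    c_segs = [Segment(s.start + n_len, s.end + n_len, s.klass, s.min_energy)
              for s in classify_segments(c_prof, cons[n_len:],
                                         min_run=min_run)]
    return AmyloidCall(region.taxon_id, classify_taxon(n_segs, c_segs),
                       n_segs, c_segs, region.provenance)


def annotate_tree_with_classes(tree: PhyloTree,
                               classes: dict[str, str]) -> PhyloTree:
    """Write per-tip amyloid classes into tree annotations (colour roles:
    high=red, low=blue, none=black)."""
    out = tree.copy()
    counts = {"high": 0, "low": 0, "none": 0}
    for tip in out.tips():
        klass = classes.get(tip.label)
        if klass is None:
            log.warning("tip %s has no amyloid class; recording 'none'",
                        tip.label)
            klass = "none"
        tip.annotations["class"] = klass
        counts[klass] = counts.get(klass, 0) + 1
    log.info("amyloid classes on tree: %s", counts)
    return out
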