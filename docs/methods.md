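# Methods

## Mass model

All arithmetic is monoisotopic (Orbitrap-class acquisition). Elemental and
residue masses come from pyteomics' NIST-derived tables; the proton mass is
the CODATA value 1.00727646677 Da. A peptide's neutral mass is the sum of
its residue masses plus one water, plus any modification deltas; the ncAA
position contributes a user-supplied residue mass instead of a canonical
one. The cross-linked conjugate of bait α and prey β has

    M = m(α) + m(β) − m(leaving group),

the leaving group defaulting to HBr (79.92616 Da) for alkyl-bromide
chemistry and configurable for other halides. No published residue mass
exists for the alkyl-bromide ncAA itself, so it is a required run parameter;
the synthetic generator uses an O-(3-bromopropyl)-tyrosine-like stand-in
(tyrosine residue + C3H5Br ≈ 283.0208 Da) computed from the elemental table
at run time. Isotope-envelope prediction and precursor isotope-error
correction are not modelled; precursor matching is strict.

## Digestion

Cleavage rules are (residue set to cut after, residue set that suppresses
the cut when following). Trypsin cuts after K/R, suppressed before P by
default (the no-P convention is switchable, since published searches often
omit it); Lys-C cuts after K. Peptides carry 0–3 missed cleavages by default.
The sequential double digestion models the His-tag re-enrichment used to
purify cross-linked peptides: a complete first-protease digest, a
retained-peptide predicate (e.g. "carries the C-terminal tag"), then the
second protease on the retained material. Coordinates are 1-based inclusive
throughout. Length bounds (default 5–60) are applied at digestion time;
mass bounds (default 500–6000 Da) at index construction, where neutral
masses are computed anyway — `digest()` itself defaults to no bounds so its
behaviour on small worked examples is exactly the rule's definition. The
ncAA position is marked with a placeholder letter ("U") that no protease
recognizes, so an ncAA substituting K or R correctly stops being a cleavage
site. N-terminal Met is not stripped.

## Search

The prey index holds every target and reversed-decoy peptide containing at
least one residue from the reactive set {C, D, E, H, K, S, T, Y}, expanded
over variable Cys carbamidomethylation (+57.02146, at most 3 mods/peptide),
sorted by neutral mass for binary-search lookup. For a spectrum at charge z
(precursors 3–7), candidates are all (bait variant, prey, reactive site)
triples whose conjugate mass matches the observed neutral within 10 ppm of
the theoretical; a carbamidomethylated Cys cannot simultaneously be the
cross-link site, and the ncAA position cannot carry a modification.

Fragments are b/y ions of both chains at charge 1–2. A fragment whose span
covers its chain's link site carries the full partner chain minus the
leaving group (the conjugate bond survives HCD). Matching is greedy over
ions sorted by m/z, each taking the lowest unused peak within 20 ppm — the
optimal greedy for interval bipartite matching, which makes matched counts
monotone in tolerance and peak count. The per-ion chance probability p is
(number of peaks × window width at the mean theoretical m/z) / spectrum
span, clamped to [1e-6, 0.5]; the chain score is −log₁₀ P[Binom(N, p) ≥ k]
evaluated with logpmf + logsumexp so near-complete matches are not flattened
by floating-point underflow of the tail. A reportable PSM needs at least one
matched fragment on each chain (configurable); this suppresses linear
peptides masquerading as cross-links. Site localization rescoring all site
variants of a pair reports the argmax and the score margin to the runner-up;
an exact tie is reported as an ambiguous site set rather than resolved
arbitrarily. Rank-1 selection per spectrum breaks score ties by smaller
absolute precursor error, then lexicographic peptide order, for determinism.

## FDR

Decoys are whole-protein sequence reversals, searched identically. With
rank-1 PSMs sorted by score, the estimate at threshold s is
(#decoys ≥ s + 1)/#targets ≥ s, tied scores sharing one threshold, and
q-values are the running minimum from the top. The +1 correction is the
default because this package's own entrapment calibration (ten independent
runs against databases padded with 50% shuffled sequences) showed the plain
ratio to be anti-conservative under rank-1 competition — realized FDP 0.063
at a nominal 5% cut, the known small-sample bias of decoy counting; with the
correction the realized FDP is statistically compatible with 5%. The plain
estimator remains available (`plus_one=False`). Accepted PSMs collapse to
unique cross-linked peptides keyed on (bait peptide, mods, prey peptide,
locus, site, mods) — the most granular reading of "cross-linked peptide" —
with the best-scoring PSM as representative; binders are the distinct prey
proteins.

## Downstream summaries

Reactivity tables count unique peptides per localized site residue;
ambiguous-site peptides go to a separate bucket rather than being split.
Motif windows are ±15 residues around each accepted site (31-mers, site at
position 16), padded with '-' at protein termini; the position frequency
matrix counts non-pad residues per column, and log-odds are
log₂((count + 1)/(n + 20) / background) with a pseudocount of 1 to avoid
log 0, background frequencies taken from the full target database. Motif
discovery itself (EM over the windows) belongs to external tools such as
MEME; the package exports pad-stripped window FASTA for them. Restraint
export writes one line per accepted (prey protein, residue), pairing it with
the bait's ncAA position under a configurable distance bound (default 15 Å,
a generous span for the ncAA side chain plus the nucleophile reach — the
appropriate bound depends on the ncAA's linker length).

## Synthetic data

The generator emulates the statistical structure of a real GECX-MS run at
desk scale. Default study conditions: 200 random proteins (lengths
N(300, 80²), minimum 60; average-proteome residue frequencies), one
120-residue bait with the ncAA placed inside a mid-length tryptic peptide,
150 implanted cross-links with site residues drawn from a Cys-dominant
prior (C 0.70, the other seven nucleophiles 0.30/7 — the qualitative
Cys:non-Cys ratio observed for alkyl-bromide ncAA reactivity), precursor
charges uniform on 3–7, fragment and precursor m/z error N(0, 3 ppm),
fragment dropout 0.15, Poisson(30) uniform noise peaks, and one background
scan per link scan (background_spectra_fraction 0.5). Background spectra are
linear tryptic peptides (up to 3 missed cleavages, 12–60 residues — the
larger species that charge-3+ precursor selection actually picks up), which
is what gives the score distribution the weak-match continuum a real run
has. Implanted prey peptides are fully cleaved, 6–40 residues, and safely
inside the index mass bounds, so every link is findable by construction.
Fragment intensities follow an exponential rank decay (rank assigned by
random permutation); only relative ordering matters to the score. An
entrapment option appends `entrapment_fraction × n_proteins` residue-shuffled
proteins (ENTRAP ids) guaranteed absent from the truth, giving a
false-positive oracle independent of the reversed-decoy machinery. A
planted-motif option rewrites a fraction of Cys contexts to CXXC (never
touching K/R/P, so the cleavage pattern is preserved) for motif-recovery
tests. All randomness flows from one integer seed through a single numpy
generator, and all writers use fixed numeric formatting, so outputs are
byte-identical across runs.

The noiseless reference condition (`noiseless_config`) is the ideal-spectrum
limit: no dropout, no mass error, no noise peaks, no background scans, and
no detector m/z truncation. The truncation matters: with the default
150–2000 m/z window a handful of implanted sites are mathematically
indistinguishable because every site-determining ion falls out of range, so
exact-localization claims are only meaningful in the untruncated limit.
Rendered spectra otherwise keep the 150–2000 window.

What the generator does not emulate: retention time and chromatography,
isotope envelopes, co-isolation chimeras, real peptide ionization
efficiencies, homologous sequence families, and real protein abundance
structure. Passing the synthetic benchmarks therefore demonstrates the
correctness of the mass bookkeeping, enumeration, scoring, localization and
FDR machinery under controlled conditions — not search performance on any
particular real dataset, which additionally depends on instrument behaviour
the generator idealizes.

## Problem sizes

The bundled benchmarks use 200 proteins / 150 links per run (the regression
and calibration suites), with ten independent seeds pooled for the
entrapment calibration; the acceptance script pools six. These sizes give a
few hundred accepted PSMs per calibration estimate — enough for the binomial
interval around the 5% target to be a meaningful check — while keeping each
full run to well under a minute.

## Known limitations

Only inter-molecular bait–prey links are searched: loop-links, mono-links
(hydrolyzed ncAA dead ends) and linear peptides are out of scope, and
dead-end species are not modelled in the simulation either. Scoring is
parameter-light by design; no attempt is made to reproduce any specific
published engine's score or PSM lists. mzML support is read-only; MGF is
the interchange format. Protein-level FDR is not computed.
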