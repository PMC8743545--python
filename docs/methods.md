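# Methods

## Scope and model

`lintopo` analyses a derivative bacterial strain against its parental
multi-replicon reference from paired-end shotgun reads. The underlying
biology: linear actinomycete replicons end in terminal inverted repeats
(TIRs) replicated via terminal proteins; when the genes required for
end-replication are lost (e.g. with a cured megaplasmid), a chromosome can
only survive by circularizing, which is accompanied by loss of terminal
segments. Three observable signals drive the analysis, all computed from
alignments of the derivative's reads to the *parental* reference:

1. **Breadth and depth of coverage per replicon.** A lost replicon shows
   near-zero breadth; a retained one near-complete breadth. Depth ratios
   against the chromosome estimate plasmid copy number.
2. **Coverage cut-offs on the chromosome.** Retained positions form a
   contiguous block [L, R]; positions outside it are deleted.
3. **Split alignments across the fusion point.** A read or contig from a
   circularized chromosome that spans the junction aligns as two segments:
   one ending at R, one starting at L, with consecutive query intervals.

All interfaces use 1-based inclusive coordinates, matching how genome
coordinates are printed; half-open arithmetic never escapes a function.

## Pipeline stages and parameters

### Mapping (built-in seed-and-extend)

The built-in mapper exists so the pipeline is self-contained and its
coordinate semantics fully specified; production alignments (e.g. from bwa)
can be imported as SAM instead, and the two routes give identical
downstream calls on the same placements.

* `k = 31` (exact-match seed length, 2-bit packed into uint64). 31-mers are
  effectively unique in multi-megabase high-GC genomes outside repeats.
* Seeds are taken at the read's start, middle and end (arbitrary-length
  queries use a ~16 bp seed stride), candidates extended ungapped with
  score +1 / −3, keeping the best-scoring block per candidate diagonal
  (Kadane over the match/mismatch profile, computed with running-minimum
  prefix sums). The −3 penalty means extension tolerates < 25% local
  mismatch density, comfortably above the simulated substitution rate while
  stopping dead at a junction breakpoint.
* `min_anchor = 50` bp: shorter blocks are too noisy to serve as junction
  evidence. `max_mismatch_rate = 0.05` per block.
* Indels are not modelled: the analysis consumes positions and depth, for
  which ungapped blocks on short reads suffice; indel-rich data should come
  in as SAM.
* **Multi-mapping ties.** Reads falling wholly inside a TIR match both ends
  of their molecule exactly. The tied placement is chosen by a
  deterministic hash (CRC32) of the read id, flagged `ambiguous`, and
  excluded from junction evidence. Hashing (rather than, say, always the
  lowest coordinate) spreads tied reads evenly over the tied loci, so both
  TIR copies keep their expected coverage and intact termini are not
  misread as deletions; determinism is preserved because the choice depends
  only on the read id.
* Circular references are indexed on a doubled sequence; placements are
  reported modulo n and split at the origin when they wrap.

### Coverage, census

`depth[i]` counts segments whose reference interval contains i; by
construction Σdepth equals the total aligned reference bases (a conserved
quantity asserted in tests). Copy number uses a **trimmed mean**
(`end_trim = 150` bp, one read length) because linear replicons are
mechanically under-covered over roughly a read length at each terminus and
PCR library spikes would otherwise bias the ratio. Presence thresholds:
breadth ≥ 0.95 (at `min_depth = 1`) is present, ≤ 0.05 absent, else
partial — an operationalisation of the qualitative dichotomy between
"complete coverage" and "no coverage", with room for terminal dips. The
published per-replicon coverage table does not state its exact depth
statistic; the trimmed mean is this package's declared choice.

### Boundaries

The left boundary is the smallest position p with depth ≥ `min_depth`
over a sustained run [p, p + `min_run` − 1] (`min_run = 100`); the right
boundary is symmetric. Keying on sustained runs rather than the first
covered base makes the boundary robust to stray coverage peaks beyond it
(chimeric or PCR artifacts, possible unresolved rearrangements); such
peaks are surfaced as warnings, never as calls. A boundary within
`terminal_dip = 150` bp (one read length) of the terminus snaps to the
terminus: that much under-coverage is expected at intact linear ends. If
no run exists the replicon is effectively absent and boundary detection
raises.

### Junctions and the call

Junction evidence requires two same-strand segments of one query, ordered
right-anchor-then-left-anchor along the strand-normalised query, anchors
≥ `min_anchor`, query intervals consecutive within `max_junction_gap = 10`,
and both endpoints inside `terminal_window = 200` kb of the respective
terminus (large enough to cover ~100 kb-scale terminal deletions with
slack).

Evidence is clustered on **canonical** coordinates: when the two anchors
overlap on the query (negative gap — microhomology at the fusion point,
i.e. the bases just inside one end happen to match the sequence at the
other), the shared bases are assigned to the right anchor by advancing L.
Without this, both anchors count the homologous base and the reconstructed
circle would carry a duplicated base. Clusters within `tolerance` of each
other merge (support-weighted); a cluster is decisive with ≥
`min_evidence = 2` independent queries or one query with both anchors ≥
`long_anchor = 500` bp — a single long assembled contig is as convincing
as multiple reads. The call is:

* **circularized** if a decisive cluster lies within `tolerance = 300` bp
  (two read lengths, the precision limit of coverage cut-offs) of both
  boundaries — the junction's base-pair-exact (L, R) then overrides the
  cut-offs, and residual disagreement > 10 bp is flagged;
* **terminal_deletion_only** if boundaries show loss but no decisive
  junction exists — deletion is established, circularization remains open
  rather than being forced to a binary;
* **intact** otherwise. Two decisive clusters disagreeing by more than the
  tolerance raise an explicit ambiguity error.

Deletion sizes in kb round half away from zero, which reproduces printed
kb figures from printed coordinates exactly.

### TIR finder

Best ungapped local alignment (+1/−2) between the first `window = 2000` bp
and the reverse complement of the last `window` bp, over all diagonals
(the diagonal matrix is sheared so every diagonal is scanned with the same
vectorised running-minimum prefix-sum block search as the mapper).
Ungapped scoring keeps "differences" a well-defined mismatch count;
identity is rounded to integer percent. Reported blocks need length ≥
`min_len = 30` and identity ≥ `min_identity = 90`%. Bookkeeping fields
reconstruct the idealised repeat: `right_truncation` counts repeat bases
missing because the right terminus stops short; `left_offset` counts bases
of the left window before the repeat starts. A planted repeat can be
reported a few bases longer than planted when the flanking bases extend
the inverted symmetry by chance (~29% per base at 70% GC) — this is a
property of the sequence, not an error.

### Spacer design

Protospacers are all 20-mers immediately 5′ of an NGG on either strand of
the target region. The off-target screen is an explicit Hamming contract:
count genomic sites (both strands, all replicons, overlaps collapsed per
(replicon, strand, start)) within `max_mismatches = 2` of the spacer that
carry a PAM, excluding the on-target site. The published design step used
BLAST screening without printed thresholds; a Hamming contract was chosen
because it is exactly checkable against brute-force enumeration. An
optional stricter seed-region rule (no mismatches in the 12 PAM-proximal
bases) reflects common Cas9 practice and is off by default. Candidates
surviving with zero hits are ranked by fewest near-miss sites (at
`max_mismatches + 1`), then position — deterministic and reproducible.

## The simulator

The generator emulates the data regime of a megaplasmid-bearing
actinomycete genome project: replicons at 70% GC; planted exact TIRs
(last t bases = reverse complement of the first t); strains derived by
whole-replicon loss and/or circularization with terminal deletions; pairs
with normal insert sizes (mean 500 bp, sd 50, truncated at the read
length), uniform substitution errors (default 0.5%), and Poisson pair
counts of mean `depth × n / (2 × read_len)` per replicon scaled by its
copy number. Fragments on linear replicons lie wholly inside the molecule,
which mechanically depresses terminal depth the way real shotgun data
under-covers linear-replicon ends; circular replicons are sampled across
the origin.

The shipped fixture preserves the size hierarchy of the real system at
desk scale: a 500 kb chromosome, a 50 kb plasmid at one copy, a 5 kb
plasmid at two copies, TIRs of 400 bp, 50× depth, 150 bp reads. The cured
circularized strain drops the large plasmid and deletes 7,334 / 8,588 bp
terminally — the published clone's losses scaled proportionally from the
6.75 Mb chromosome.

Deliberately **not** modelled: quality scores, indels, PCR-duplicate and
GC-coverage bias (observed in the real libraries but never corrected for
in the analysis, and no quantitative model of it is published), and
long-read error profiles. Passing tests therefore demonstrate correctness
of the inference logic under substitution noise and exact replicon
structure; they do not demonstrate robustness to indel-rich alignments or
library-preparation artifacts, which should enter via SAM from a
production mapper.

## Verification strategy and problem sizes

Unit tests pin every operation to hand-computable cases and published
worked examples (printed junction coordinates, deletion sizes, the
genome-loss percentage). Independent brute-force oracles — per-diagonal
scalar Kadane for the TIR finder, exhaustive Hamming scans for the spacer
screen, substring search for simulated reads — are implemented separately
in the test suite and compared exactly. The recovery study runs the full
pipeline on 20 seeds of the fixture's cured circularized strain (calling
status, junction coordinates within ±150 bp, presence/absence) plus 20
seeds of a copy-number scenario (200 kb chromosome, three 40 kb plasmids
at 0.2 / 1 / 2 copies, 30× — sizes chosen so Poisson depth noise sits well
inside the ±15% acceptance band). These sizes keep the default suite at
roughly two minutes on one core while leaving every statistical margin
wide.

## Known limitations

* Ungapped extension only; indel-containing junction reads will anchor
  shorter or split — import production alignments for such data.
* One junction per chromosome is modelled; multiple simultaneous
  rearrangements surface as an ambiguity error or as
  beyond-boundary-coverage warnings, not as calls.
* Copy-number estimates inherit any real-library coverage bias; the
  trimmed mean guards only against terminal dips and isolated spikes.
* TIR reports are the best single ungapped block; biological TIRs with
  internal indels would be fragmented or shortened.
* The off-target screen is Hamming-only (no DNA/RNA bulges) and treats all
  mismatch positions equally unless the seed-region rule is enabled.
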