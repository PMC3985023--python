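# Methods

## The model

`ppma` treats gene-function assignment as an evidence-combination problem.
Two descriptor families provide largely independent evidence for an
enzymatic function:

* **GO terms** ("profiles") attached to a gene by domain-based annotation;
  flexible, covering anywhere from a motif to the full sequence, with known
  electronic-annotation error rates;
* **PROSITE consensus patterns** ("patterns"), short exact signatures
  (typically 10–25 residues) with per-pattern true/false-positive behaviour.

Either source alone produces false positives; requiring a gene to carry two
or more descriptors from the translated POI lists — whether two GO terms, two
patterns, or one of each — selects the intersection regime where annotation
errors must coincide to produce a false call.  The pipeline is therefore
deliberately precision-first: every ambiguous choice below errs toward
rejecting a gene.

### Translation

E.C. numbers are parsed as four concrete fields, with a wildcard permitted
only in the serial field (a wildcard elsewhere is a parse error, since
expansion over the first three fields would explode the search far beyond a
POI family).  Wildcards expand against the loaded enzyme table; duplicates
are removed preserving first occurrence; entries whose status is
preliminary (ENZYME `n`-suffixed serials), transferred, or deleted are
excluded and logged.  The surviving entries' GO and PROSITE cross-references
are unioned in first-occurrence order.  Three PROSITE signatures
(PS00198, PS00455, PS00143) are excluded by default as too unspecific to
serve as function evidence; the exclusion list is a parameter.  Non-enzyme
POIs (no E.C. number) enter through supplemental descriptor arguments.

### Pattern engine

The pattern grammar supports fixed residues, `[...]` allowed sets, `{...}`
forbidden sets, `x`, `(n)`/`(n,m)` repeats on any element, `<`/`>` anchors
and the terminal dot.  The matcher is a per-start dynamic program over
element reach sets; it reports **every** distinct (start, end) span rather
than first-only or leftmost-longest, because downstream filtering consumes
presence/absence only and exhaustive reporting makes the matcher exactly
checkable against a brute-force enumeration oracle (the test suite and the
acceptance run compare the two on ~1000 random pattern/sequence pairs).
Ambiguity codes are handled conservatively: `X` in a sequence satisfies only
`x` elements; `B` and `Z` satisfy neither fixed nor bracketed elements nor
`{...}` sets.  A permissive reading would manufacture matches from
low-quality sequence — the failure mode the pipeline exists to avoid.  The
`[...>]` C-terminal-or-residue idiom is rejected with an explicit
unsupported-syntax error.  Coordinates are 1-based inclusive throughout
(PROSITE convention).

### Gene-fragment filter

Genes shorter than **300 nt** or not explicitly annotated `complete` are
removed before evidence is counted.  When a table lacks nucleotide lengths,
length is derived as 3·aa + 3 (codons plus stop).  A missing completeness
value counts as incomplete (conservative).  The filter is idempotent and
commutes with the descriptor filters; the command-line runner applies
descriptor filters first by default (so raw-hit counts can be audited) and
offers `--fragment-filter-first` to swap the order.

### Set building and ranking

De-duplication collapses an arbitrary multiset of hit rows (warehouse
exports repeat gene–descriptor evidence, one row per annotation source) into
one entry per gene with the full sorted descriptor combination.  Genes with
identical combinations form a PPM set; a gene carrying both descriptor kinds
belongs only to the profile-and-pattern class, never to the pure classes —
this disjointness is what makes the three classes a partition of the
non-redundant genes.  Sets are ranked by descriptor count (the reliability
signal), then member count, then lexicographic combination; the two
tie-breaks are this package's convention, chosen to make ranking a total,
input-order-independent function.  Condensation into enzyme-family meta-sets
is driven by an explicit curator-supplied map from descriptor combination to
family label; the package never guesses family identity, because that
judgment (e.g. that three subtilase active-site signatures describe one
protease family, or that two disjoint pairs of component signatures both
describe nitrogenase) is biological, not combinatorial.

### Pattern derivation

For families without public descriptors, a pattern is derived from an
archetype with structurally characterized functional residues
(metal-binding / catalytic / structural role tags) plus candidate homologs,
all in one alignment.  At each functional position the observed residue set
across sequences becomes a fixed element (singleton), an `[...]` class
(small set), or — beyond the **breadth threshold, default 4 residues** —
degrades to `x`, the operational reading of "this position is not generally
important".  Spacers between surviving positions take the observed
min/max residue counts, so candidate deletions widen `x(n)` to `x(n,m)`
naturally.  Every derived pattern is verified against all input sequences
via the pattern engine before it is returned; derivation is deterministic.
Role tags do not alter the algorithm but are carried into the derivation
report so a curator can overrule individual substitutions.  `relax_pattern`
widens an existing pattern minimally for newly observed exceptions and is
guaranteed monotone (the match set only grows).

### Phylogenetic selection

Within a set, aligned members are compared under **complete deletion**
(every column containing a gap, `?`, or a non-standard letter in any
sequence is dropped globally), giving p-distances corrected to
d = −ln(1 − p) substitutions per site (Poisson model: equal rates, no
back-substitution accounting beyond the log correction; a saturated pair
p = 1 is an error rather than an arbitrary cap).  Trees are built by
Neighbor-Joining with a deterministic tie-break (smallest pair of
smallest-descendant-leaf labels) and negative branch lengths clamped to
zero with the deficit logged.  Clusters are the leaf components after
cutting branches longer than a threshold, **default 0.1 substitutions per
site** — the magnitude at which within-isoenzyme variation typically ends in
these data; the cut is a parameter because no universal criterion exists.
Representatives are chosen by a cascade: (1) a unique member whose aligned
residues cover every other member (the "contains all shorter ones" case);
(2) the best externally supplied similarity score (an injected table, e.g.
from a BLAST run — kept external so the package has no alignment-search
dependency); (3) the most functional-side-chain residues, with the set fixed
to {C, D, E, H, K, N, Q, R, S, T, W, Y} (hydrogen bonding, metal
complexation, acid/base side chains).  Ties end at the lexicographically
smallest gene id, and the winning rule is reported.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| `min_nt` | 300 | nucleotides | minimal length for a functional product; boundary is ≥ 300 kept |
| low-specificity exclusions | PS00198, PS00455, PS00143 | — | patterns too unspecific as function evidence |
| reliability threshold | 2 | descriptors | two independent evidences per gene |
| derivation `breadth` | 4 | residues | larger observed classes degrade to `x` |
| cluster `threshold` | 0.1 | substitutions/site | branch cut separating isoenzyme clusters |

## Synthetic fixtures: what they show and what they cannot

The generators (`ppma.synthetic_fixtures`) are first-class, tested code.
The replay collection reproduces a study-scale screen *structurally*: the
exact descriptor combinations and member counts of the published set table,
fragmentary genes sized so the filter trajectories (520→352→106 profile,
1617→1078→142 pattern hits) emerge from the pipeline, and duplicated
evidence rows emulating warehouse exports.  Planted-protein fixtures
guarantee, by rejection sampling against the matcher itself, that background
sequences contain no accidental matches, making scan-mode truth tables
exact.  Cluster alignments plant a known partition with controlled
within/between mutation rates (defaults 0.02 / 0.4 per site over 200
columns, cluster sizes 5+4+3+2).

What passing these fixtures does **not** show: real SAG data have MDA
amplification bias, chimeric contigs, frame errors and annotation noise
none of which the generators simulate; real PROSITE patterns have
empirical false-positive rates that synthetic uniform backgrounds cannot
exhibit; and the uniform-residue background understates low-complexity
regions where short patterns over-match.  Results on real collections
therefore depend on annotation quality in ways the test suite cannot
certify.

The derivation fixture encodes the candidate variation a relaxed
carbonic-anhydrase-style pattern must admit — a one-residue spacer deletion
in all candidates, two tolerated substitutions, one conservative acidic
swap, one hypervariable position — and deliberately excludes substitutions a
curator would judge function-breaking, since a pattern derived from
evidence it cannot match would be unsound.

## Numerical and degenerate-input choices

* Ordered sets everywhere (first-occurrence order) so outputs are
  reproducible and diffable.
* Empty wildcard expansions warn rather than fail; unmapped concrete E.C.
  numbers are recorded, not errors.
* Zero flagged genes make reliability rates `None`, never 0 — an undefined
  rate printed as zero would masquerade as a perfect false-positive score.
* NJ requires ≥ 3 leaves (a pair has a single forced edge; callers handle
  it directly); the final three nodes are resolved around the central
  vertex, yielding a trifurcating root for the unrooted topology.
* Fragment filtering with unresolvable length is impossible by construction
  (records must carry nt length, aa length or a sequence).

## Problem sizes

The test suite and the acceptance script run at desk scale: the 941-gene
replay collection, 60 planted proteins, 1000 random pattern/sequence oracle
pairs, 100 random 4–8-leaf trees and one 14-leaf planted-cluster alignment —
sizes at which every expected value is exactly computable by an independent
oracle.  The pipeline itself is linear in genes × descriptors and handles
database-scale inputs; nothing in the implementation is fixture-specific.

## Known limitations

* GO terms are matched as literal identifiers; no ontology-graph ancestor
  propagation (a gene annotated with a child term does not hit a parent
  term in the profile list).
* PROSITE profiles (weight matrices) and the ScanProsite web dialects are
  out of scope; only consensus patterns are supported.
* Pattern syntax cannot express a spacer that is sometimes absent next to
  a nonzero spacer (`x(0,n)` is rejected); derivation reports this case as
  an error instead of silently merging elements.
* The Poisson correction ignores rate heterogeneity across sites; for
  deeply diverged set members a Gamma-corrected or model-based distance
  would be preferable before trusting fine cluster structure.
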