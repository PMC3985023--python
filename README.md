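# ppma — profile and pattern matching for reliable enzyme-function identification

Homology-based annotation of genomes from poorly characterized organisms —
single amplified genomes (SAGs) of extremophiles are the motivating case —
produces enough false positives to sink an expression campaign: synthesizing
and characterizing one wrongly annotated halophilic gene costs weeks, while a
missed gene costs nothing.  `ppma` implements a profile-and-pattern matching
(PPM) strategy that trades recall for precision by demanding *independent*
descriptor evidence before a gene is called a protein of interest (POI).

The workflow:

1. **Translate** a POI list given as Enzyme Commission numbers (wildcards in
   the serial field allowed, e.g. `1.1.1.*`) into two orthogonal descriptor
   lists, using ENZYME-release and ec2go-style mapping tables: a non-redundant
   set of GO terms (the *profile* filter) and a non-redundant set of PROSITE
   consensus patterns (the *pattern* filter).  Preliminary, transferred and
   deleted E.C. entries are dropped, as are patterns known to be unspecific.
2. **Match** both lists independently against an annotated gene collection
   (or, in scan mode, match the pattern syntax directly against protein
   sequences with the built-in PS_Scan-style interpreter), then remove
   unreliable gene fragments (shorter than 300 nt or not annotated complete).
3. **Process**: de-duplicate hits into one entry per gene, group genes by
   their exact descriptor combination into PPM sets (classes *profile*,
   *pattern*, *profile-and-pattern*), rank by descriptor count, flag sets with
   ≥ 2 descriptors as reliable, and optionally condense sets into curated
   enzyme families (meta-sets).
4. For families lacking public descriptors, **derive** a relaxed consensus
   pattern from an archetype's functional residues and candidate homologs;
   for crowded sets, **cluster** members phylogenetically (Poisson-corrected
   distances d = −ln(1 − p) under complete deletion, Neighbor-Joining,
   branch-length cut) and pick one expression representative per cluster.

## Worked example

The packaged generators reproduce a study-scale campaign end to end.  The
replay collection holds 941 genes whose descriptor combinations, fragment
statistics and duplicated evidence rows mirror a published SAG screen:

```python
from ppma.gene_store import gene_fragment_filter
from ppma.ppm_core import build_ppm_sets, condense_meta_sets, dedupe_hits, filter_hits
from ppma.synthetic_fixtures import make_replay_collection

fx = make_replay_collection(seed=1)
kept = gene_fragment_filter(fx.collection)
profile = filter_hits(fx.profile_hits, kept)
pattern = filter_hits(fx.pattern_hits, kept)
print(len(fx.profile_hits), len(profile), len(dedupe_hits(profile)))
print(len(fx.pattern_hits), len(pattern), len(dedupe_hits(pattern)))

sets = build_ppm_sets(dedupe_hits(profile + pattern))
reliable = [s for s in sets if s.reliable]
print(sum(len(s.members) for s in reliable),
      len(condense_meta_sets(reliable, fx.family_map)))
```

prints

```
520 352 106
1617 1078 142
117 9
```

— 520 raw profile hits shrink to 352 on complete genes and 106 non-redundant
genes; 1617 raw pattern hits to 1078 and 142; the 117 genes backed by at
least two descriptors condense into 9 enzyme families.  The same pipeline is
available from the shell (`ppma translate`, `ppma run`, `ppma scan`,
`ppma derive-pattern`, `ppma cluster`); `ppma run` writes ranked set reports
plus a `stage_counts.json` ledger with every count above.

Deriving a custom pattern for a family without public descriptors (the
gamma-carbonic-anhydrase scenario: an archetype plus six candidate homologs):

```python
from ppma.pattern_derivation import derive_pattern
from ppma.synthetic_fixtures import make_gamma_ca_fixture

for dp in derive_pattern(make_gamma_ca_fixture(seed=1).spec):
    print(dp.pattern.render())
```

prints

```
R-x-D-x(10,11)-[NC]-x-[QK]-x(5)-H-x(2)-[ED]
H-x(3)-H
```

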