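# Methods

## The structure-identifier language

An *O*-glycan is a rooted tree of residues hanging off a protein-linked
GalNAc.  Identifiers write this tree over a one-letter alphabet — `f`
Fuc, `K` Kdn, `L` Gal, `N` Neu5Gc, `S` Neu5Ac, `V` GalNAc, `Y` GlcNAc,
`s` sulfate — read right to left from the reducing end.  Every residue
except the root carries the linkage position on its parent (2, 3, 4, 6;
8 is accepted by the grammar but produced by no rule), optionally
preceded by an anomeric letter `a`/`b`.  Branches are bracketed, and
every substituent of the root GalNAc is written as a branch, so core 1
is `[L3]VT`, not `L3VT`.

The parser is a hand-written recursive descent over this grammar.  It
accepts any bracketing and sibling order the grammar allows and reports
0-based character offsets for unbalanced brackets, illegal symbols or a
missing trailing `T`.  Chemical feasibility is checked separately:
a grammatical string such as `[S3][L3]VT` (two residues 3-linked to one
GalNAc) parses but is flagged by `validate_chemistry`.

**Canonical form.**  Anomeric letters are dropped (each enzyme's product
stereochemistry is fixed, so they carry no information); sibling
branches are ordered by descending linkage position left to right, which
reads as ascending right to left; modifier branches (fucose, sulfate)
sit innermost, adjacent to the residue they decorate, fucose outside
sulfate.  When a residue carries several structural (non-modifier)
children, a 6-linked child forces the fully bracketed form — the
I-branch convention `[[Y6][Y3]L4…]` — and otherwise the lowest-position
child continues the chain in-line, which yields the conventional
`S3[V4]L` form of the Sd(a) epitope.  Those are the only two multi-child
cases the rule set can reach.  Canonicalization is idempotent and
independent of the input's branch order; serialization inverts parsing
on canonical strings.

**IUPAC translation** follows the condensed one-line convention: the
lowest-position child is the main chain, other branches are
parenthesized before their parent, and sulfation is written as a
`(3S)`/`(6S)` prefix on the sulfated residue.  Anomeric configurations
are filled in from the enzyme defaults: fucosyl and sialyl links α; Gal
and GlcNAc β; GalNAc α, except the β1-4 GalNAc of the Sd(a) synthase;
the one α-Gal is the 3-linked Gal of the B antigen.

## Enzyme rules

Each of the 25 activities is an acceptor template plus a single added
residue at a fixed position; removal of exactly that residue defines the
reversed rule, so forward and per-site reverse application are exact
inverses and every reaction network is a DAG whose edges add one residue.

Templates compile to subtree patterns, never substring searches.  The
semantics, stated once:

* a *branch-initial* (terminal) residue in a template may carry only
  substituents from the rule's tolerance set.  The default tolerance is
  sulfate alone — sulfation never blocks the transferases — while
  structural sugars always block;
* *inner* template residues may carry extra branches from a per-rule
  tolerance set.  Fucose is tolerated where the terminal epitopes demand
  it (the sialyltransferases of rules 4 and 16 must accept
  fucose-decorated acceptors, or sialyl-Lewis X/A and Lewis B/Y could
  never form) and not where it must block (rule 10 must not elongate a
  fucosylated LacNAc, or internally fucosylated chains would become
  constructible);
* a site yields a product only when the target position is free, so no
  rule can create a position conflict;
* rules whose written acceptors end at the reducing end are anchored at
  the root GalNAc; wildcard-ended acceptors bind anywhere.

Departures from the literal written equations, each forced by published
structures the literal form cannot produce, are: rule 7 (β3Gn-T3)
elongates the core-1 Gal whatever the state of the 6-arm (extended
core-1 chains are well documented); rule 14 (ST6GalNAc-I) 6-sialylates
the root GalNAc with an arbitrary 3-arm (sialyl-6 core-3 structures are
experimentally observed and must be deconstructable), which makes rule
17 redundant; rule 4 (α2Fuc-Ts) also acts on type-2 chains (Lewis Y and
type-2 A/B antigens require it; switchable via `PanelConfig`);
rule 21 (GAL3ST2) sulfates only the β3-Gal on GlcNAc, not the α3-Gal of
the B antigen.

**I-branch inhibition.**  Poly-LacNAc elongation (rule 10) is inhibited
by the I-branching enzyme's product.  The scope of that inhibition is
genuinely open; the package implements four readings behind
`PanelConfig.gcnt2_inhibition` — `branch6` (default: the 6-branch the
I-branching enzyme created is a poor elongation substrate, so rule 10
is blocked below it), `local` (both branches of an I-branched Gal),
`global` (any I-branch anywhere blocks the rule) and `off`.  The default
was selected by calibration against the published network counts and the
full epitope table (see below).

**Multi-site application** yields one product per matched site
(`apply_forward(..., multi_site="per_site")`, the default).  The
alternative simultaneous policy (all sites of one acceptor form
substituted at once) is implemented for comparison; it prunes the
asymmetric diantennary intermediates and was rejected by calibration.

Donors are treated as unlimited and no kinetics are modelled; products
are deduplicated by canonical identifier, and enzyme order within an
iteration (ascending rule id) is observable only in log serial numbers.

## Simulation and prediction

Forward simulation is breadth-style: products first seen at iteration
*n* are the substrates of iteration *n*+1; the run stops at an iteration
cap or at the first iteration adding no new structure.  A network
"closed after *N* iterations" produced its last new structure at
iteration *N* (`closure_iteration`); `closed_at` records the following,
empty iteration.  An optional cap on GlcNAc residues per glycan closes
otherwise exponentially growing networks at every cap value.  A node
ceiling (default 2×10⁷) guards against runaway runs.  Everything is
deterministic: identical configurations give identical node, edge and
serial assignments.

Two iteration conventions appear in the reference record and are kept
apart deliberately: the headline structure count is quoted for eight
iterations starting at the Tn antigen, i.e. nine engine iterations from
the bare site with the initiation reaction counted; closure and
epitope-table experiments quote engine iterations from the bare site.

Reverse prediction applies the inverted rules to a shrinking pool,
removing one residue per reaction, and stops when the bare site appears
— which happens exactly when the last step removes the protein-linked
GalNAc — or when an iteration adds nothing.  Because every reverse step
removes one residue, a predictable *n*-residue glycan is reached in
exactly *n* iterations.  `forward_from_prediction` reruns the forward
simulator restricted to the enzymes the reverse network used; the
predicted glycan necessarily reappears as a node.

## Analytics

Connectivity is summarized by β = e/v, the non-planar cyclomatic ratio
α = (e − v + 1) / (v(v−1)/2 − (v−1)) (zero for trees; undefined below
three nodes) and γ = 2e / (v(v−1)), with e counting distinct directed
substrate→product pairs.  The local clustering coefficient of node *i*
is C\_i = E\_i / (k\_i(k\_i − 1)) with k\_i the distinct neighbours
(union of in- and out-) and E\_i the directed edges among them; nodes
with fewer than two neighbours contribute zero, and ⟨C⟩ is the plain
mean over all nodes.  These choices are validated against brute-force
enumeration on random and exhaustively enumerated small DAGs in the test
suite.

Core classification reads the root GalNAc's 3- and 6-substituents
(Gal@3 → core 1, +GlcNAc@6 → core 2; GlcNAc@3 → core 3, +GlcNAc@6 →
core 4); Tn and sialyl-Tn fall outside.  Terminal epitopes (Lewis
A/B/X/Y, their sialylated forms, H, A, B, Sd(a)/Cad) are detected as
substring patterns of the canonical identifier — bracket context makes
the patterns mutually exclusive where they must be (a Lewis B arm does
not fire Lewis A).  Epitope percentages are per glycan, rounded half-up
to one decimal; a glycan may carry several labels, so rows need not sum
to 100, and "other" counts glycans carrying none.

## Knockouts and validation

A knockout run disables a rule subset and compares against the wild-type
network under the identical configuration; removal can only remove
products, so knockout networks are node-subsets of their baselines and
the difference is reported as the missing-structure set.  The packaged
epitope screen uses 12 iterations with the sulfotransferases (20–22)
omitted from the panel.  Structure validation reverse-predicts a list of
identifiers (the packaged set holds the 45 multiply-reported
experimental structures; unparseable inputs are excluded from the
denominator) and reports coverage.  A loader accepts an external corpus
when one is available; none is bundled.

## Calibration and known limitations

The written enzyme equations do not pin down matching semantics (which
decorations a pattern tolerates, and where).  The package's policy was
calibrated against the reference quantities of record: the 17-step MUC7
deconstruction using exactly nine enzymes, the 44/45 validation
coverage, the knockout closures at iterations 14 and 20 and the
β4Gal-T4 epitope row (B antigen 30.3 %) are reproduced exactly, and the
wild-type Lewis X percentage to within 2 %.  The full-panel structure
count and its core partition land close but not exactly (8,855 vs 8,930
glycans; cores 1,394 / 2,882 / 842 / 3,735 vs 1,536 / 2,828 / 1,011 /
3,553): the residual sits in deep (eight-residue) branch contents, and a
systematic search over tolerance matrices, anchoring breadths,
inhibition scopes and multi-site policies did not close it.  The tests
assert the exact reference values and the two count assertions fail
honestly under the shipped configuration.

A reported invariance — that knocking out the core-2 synthase or the
poly-LacNAc elongase leaves the 12-iteration epitope distribution
unchanged to one decimal — is reproduced exactly for the core-2 synthase
only if percentages are computed over unique branch structures rather
than whole glycans (branch sets are unaffected by pairing), and not at
all for the elongase; the per-glycan convention is used throughout
because the row-level reference values fit it best.

Other limitations: no kinetics, unlimited donor pools; the hypothetical
activities discussed alongside the model (internal fucosylation,
distal 6-sialylation, Kdn/Neu5Gc donor swaps, cores 5–8, glycosidases)
are not implemented; only the CFG symbol style is rendered, with fixed
glyph geometry; DOT output is emitted but never laid out.
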