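# Methods

This note documents the models and procedures implemented in compartnet,
the choices made where the design was genuinely open, and what the
synthetic study sets do and do not demonstrate.

## Compartment model

Eight physical compartments (E, N, C, ER, GA, X, L, M) anchored to the
standard cellular-component ontology terms, plus the placeholder `U`
(uncertain). `U` is never an analysis target: no pathway graph, gap, IRLR
or transport involves it; it only marks missing knowledge and is resolved
to cytosol before transport inference (the common convention for
unlocalized reactions in compartmentalized reconstructions).

Every reaction location carries a provenance tag — `protein`,
`default-uncertain`, `gap-filled`, `curated`, `cytosol-default` — so a
finished network records *why* each reaction sits where it does and every
stage is auditable and re-runnable. Protein-reaction links are
soft-deleted (an `active` flag), which keeps deleted-relationship reports
reproducible from the model itself.

Stoichiometry is parsed and stored but only presence and role (substrate
vs product) drive the algorithms; the procedures are purely topological.

## Ontology backtracking

A protein annotated to a sub-organelle term is resolved by ascending
`is_a` and `part_of` edges until an anchor term of the target map is
reached; the term itself counts (reflexive reachability). `part_of` is
required for membrane-to-organelle ancestry; regulatory relations are
ignored. The plasma-membrane remap to cytosol is an *extra target-map
entry*, not a special case in the traversal, so the algorithm stays
generic for synthetic ontologies. When a term reaches both an anchor and
only-above-anchor ancestors, the anchor wins: `U` is a fallback, not a
location. Obsolete terms are parsed but never traversed.

Keyword-derived locations (six organelle keywords: nucleus, ER, Golgi,
peroxisome, lysosome, mitochondrion) are resolved by the reader and merged
with ontology-derived ones; conflicts assign the protein to all locations.
No evidence-code filtering is performed; the association reader exposes
the rows as-is and a caller may pre-filter.

## Relationship types and type-c resolution

Classification uses informative enzymes only (a protein whose location set
is `{U}` carries no information and is excluded; it still contributes `U`
to reaction localization when alone). With enzymes partitioned by
identical location set: one enzyme → a; one part → b; several pairwise
disjoint parts → c; anything else → d. Equality (not mere overlap) is
required for b, and mixtures that are neither equal nor disjoint fall to
d as the safest residual class.

Which complementary part is *correct* is evidence, not algorithm: verdicts
arrive as data rows naming a compartment, and resolution deactivates the
links of every part excluding it, re-localizes the reactions and tags the
verdict compartment `curated`.

## Pathway graphs and the edge rule

For one pathway and one compartment, located member reactions are nodes;
an edge requires a shared main metabolite that can *flow* — produced by
one reaction and consumed by the other under at least one permitted
direction (reversible reactions permit both). This producer/consumer rule
is the single most consequential under-specified choice: a plain
co-occurrence rule would weld parallel consumers of one substrate together
and inflate connectivity. Co-occurrence remains available
(`edge_rule="cooccurrence"`) for sensitivity analysis.

Currency metabolites (default: ATP, ADP, AMP, NAD+, NADH, NADP+, NADPH,
FAD, FADH2, CoA, H2O, CO2, O2, NH3, orthophosphate, pyrophosphate, H+;
configurable per run and applied uniformly) never link reactions, never
carry path-search steps, and are never reported as dead ends.

Components are reported in canonical order (sorted members, ordered by
smallest member id) so outputs are byte-stable.

## Gap identification and filling

A gap is a missing reaction-location *relationship*. For every analysed
(pathway, compartment) — the catch-all "isolated" pathway and `U` are
excluded — each pathway reaction not located there is tested against each
pair of distinct components whose main-metabolite lists both intersect the
reaction's main metabolites; one record is emitted per pair, so a reaction
bridging three components yields three records but at most one fill. Gap
records count relationships; fills count distinct (reaction, compartment)
pairs.

Filling: a reaction that was location-less (`{U}`) at detection time is
filled directly (it may accumulate several compartments from gaps in
different locations — `U` is a placeholder, not a location); a located
reaction fills only when an evidence row exists, optionally adding the
newly implicated enzyme links; everything else stays `unfilled`.

## IRLR identification and decision

After gap filling the graphs are re-derived and one-node components
flagged. By default a (reaction, compartment) pair is an IRLR only when
the reaction is a singleton in *every* analysed pathway containing it for
that compartment — a reaction connected in any pathway context is
considered functional there. This conservative scope avoids deleting
supported locations; the per-pathway variant is a config switch.

Decision rules, first match wins: (1) literature *keep* evidence; (2)
*bad-link* evidence — the named link is deactivated and the reaction
re-localized from its remaining enzymes, preserving non-protein provenance
such as gap fills; (3) some catalysing enzyme has the flagged compartment
as its only location and catalyses no other reaction (active links counted
network-wide, not per pathway); (4) otherwise the compartment is removed.
A removal that would empty the location set reverts the reaction to `{U}`
(logged) — no reaction is ever left location-less.

## Curation

Literature revisions are data: ordered edit records (`delete-link`,
`add-link`, `set-locations`, `add-location`, `remove-location`) with
citations, applied atomically in order-index sequence with a before/after
audit log. Lenient mode rejects and logs bad references and continues;
strict mode aborts. `check_rules` is advisory only — the location
heuristics it encodes (metabolite-coupled compartment expectations,
carbon-chain-length thresholds) have documented biological exceptions, so
it reports and never edits. Carbon counts are an input column, never
inferred from compound names.

## Transports

Uncertain reactions move to cytosol (`cytosol-default`); a redundant `U`
beside real compartments is dropped.

Reference import: direct-evidence rows (score 3) and curated
transporter-annotation rows are accepted whenever the metabolite is known
to the network; physiological-evidence rows (score 2) only when the
metabolite participates in located *metabolic* reactions in both
compartments (previously added transports never vouch for presence);
scores below 2 are dropped. Acceptance is monotone in score.

Dead ends are computed per compartment network-wide by default (the
per-pathway variant double-counts shared metabolites and is available as a
mode): a main metabolite only produced, only consumed, or — the
`sole-participant` mode, on by default with a strict switch to disable —
confined to exactly one reaction. A single reversible reaction formally
produces and consumes its metabolites yet leaves them functionally
disconnected, which is why sole participation is flagged; reversible
reactions otherwise count as both producer and consumer, and existing
transports count at both endpoints.

Inference uses the cytosol as hub: for a dead-end metabolite present in
compartment set S (|S| ≥ 2), reversible transports C↔L are added for
every other compartment L of S. When cytosol itself holds the metabolite
this reduces to the single L↔C bridge; when it does not, the hub form is
what guarantees the connectivity contract — re-running dead-end analysis
after inference finds no dead end whose metabolite spans two or more
compartments (a lone L↔C edge would leave a sole-participant dead end in
cytosol). Inferred transports are reversible because dead-end analysis
carries no directional evidence. Transport ids are deterministic functions
of (metabolite, compartment pair); duplicates collapse with source
precedence direct reference > physiological reference > transporter
annotation > dead-end inference. Nuclear-pore style C↔N transports are not
special-cased; they emerge from inference like any other pair.

## Pipeline order and snapshots

localize → type-c revision → gap filling → IRLR revision → curation →
uncertain→cytosol → reference import → dead-end inference. Each
location-revising stage re-derives its graphs and contributes a
per-compartment snapshot column; each column sums to the total number of
reaction-location relationships at that stage. All writers sort rows, so
two runs from one seed are byte-identical.

## Synthetic study sets

The generator emulates what the algorithms consume: pathway-structured
reaction networks with enzyme links, partial two-source annotation,
currency metabolites, and planted findings with clean ground truth.

* Plain pathways are reaction *cycles* (5–10 reactions by default), so
  every main metabolite is produced and consumed — no incidental dead
  ends, one component per home compartment.
* A planted gap is a five-reaction motif — two parallel two-step branches
  plus a return reaction whose enzyme is unannotated. The home-compartment
  graph splits into exactly two components which only the uncertain return
  reaction bridges: exactly one auto-fillable gap record each.
* A planted IRLR parallels one cycle step; its single enzyme carries the
  home compartment plus one off-compartment, so the reaction is a
  singleton there, and the decision rules remove it (the enzyme is neither
  location-unique nor single-reaction), leaving the home location intact.
* A planted dead end is an unbalanced side metabolite of one cycle
  reaction (mode chosen among only-produced / only-consumed /
  sole-participant), balanced inside a second, differently-homed pathway
  so transport inference has a destination.
* Enzymes left unannotated beyond the gap breakers are drawn only from
  cytosol-homed plain pathways, at most one per pathway, so the later
  uncertain→cytosol reassignment restores their metabolite balance.

Ground truth is verified post hoc by brute-force oracles (fixed-point
reachability, exhaustive gap/IRLR/dead-end enumeration) that share no code
with the detection modules; generation retries with a perturbed seed and
errors if the guarantee cannot be met. Unsatisfiable configurations
(too few pathways for the requested plantings, cycle length under 5) are
rejected with the violated constraint named.

What passing on these sets shows: the detection and decision machinery
implements its definitions exactly, deterministically, at planted
densities up to ten findings of each kind. What it does not show: behaviour
on real annotation noise (wrong rather than missing locations), promiscuous
metabolites that blur the currency boundary, multi-pathway reactions with
conflicting contexts at scale, or biologically realistic stoichiometry —
real-data runs should treat borderline findings as hypotheses for manual
review, which is why every report carries provenance and citations.

## Problem sizes and numerics

Default study sets run ~90–160 reactions across 8–25 pathways; the
acceptance script uses 14 pathways with four findings of each kind. The
algorithms are exact graph procedures — no tolerances, no floating-point
comparisons beyond stoichiometry formatting; ties are broken by sorted
identifiers everywhere. Degenerate inputs are handled explicitly: empty
pathways yield empty graphs, reactions with all-uncertain enzymes classify
as `unknown`, removals never leave empty location sets, and metabolites
confined to one compartment never generate transports.

## Known limitations

No flux or mass-balance reasoning: a gap fill that reconnects a graph may
still be thermodynamically implausible. Evidence tables drive every
non-structural decision, so the quality of a real-data run tracks the
quality of its curation inputs. The SBML export is a one-way serialization
of the finished model; arbitrary SBML import is out of scope, as are
tissue-specific expression reasoning and comparisons between
reconstructions.
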