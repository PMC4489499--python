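# Methods

## The model

An art-making session on a pen tablet emits five raw channels: the pen's
x and y page coordinates, the pressure on the stylus, and the color and
tool selections over time.  `atelier` treats the artwork's construction
as a reactive system and models it as a statechart — a state machine
with nested (hierarchical) states and orthogonal (concurrent) regions:

```
ArtRoom
├── ArtRoomSessionOff
└── ArtRoomSessionOn            (orthogonal: ArtWork ∥ Client ∥ ArtTherapist)
    └── ArtWork                 (exclusive: Idle | Materials_Selecting | Painting)
        └── Painting            (orthogonal)
            ├── Materials_Selected   (Color ∥ Tool; one leaf per palette color / tool)
            ├── Stroke_Characteristics
            │     Velocity {low, medium, high}
            │     Gradient {8 × 45° compass sectors}
            │     Pressure {low, medium, high}
            │     Size     {short, medium, long}
            └── Page_Use
                  Quarters {Q1 top-left, Q2 bottom-left, Q3 top-right, Q4 bottom-right}
                  Parts    {center, boundary}
```

`Client` and `ArtTherapist` are structural stubs: they enter and leave
with the session but have no internal dynamics here (interaction
modeling is out of scope).  Executing the statechart over a session's
event stream yields a *timed trace* — for every state, the intervals
during which it was active — from which all occupancy metrics derive.

### Event semantics

* `pen_down` enters `Painting`; all orthogonal regions are entered at
  once with values from the first sample window.  `pen_up` exits to
  `Idle`.
* `select_color` / `select_tool` outside a stroke enter
  `Materials_Selecting`, which persists until the next `pen_down` (or
  session end); the part of an inter-stroke gap before any selection is
  `Idle`.  A selection during a stroke only updates the pending
  material — the current stroke keeps the materials it started with.
* A session without an explicit `session_end` is closed at its last
  event with a warning, as is a stream that ends mid-stroke.

### Kinematic classification

Per-sample kinematics use the trailing two-sample window (current minus
previous sample); the first sample of a stroke inherits the second's
classification, and each classification holds from its sample to the
next one (left-sample hold).  The consequence worth knowing: the state
time attributed to a class can differ from the exact geometric time by
at most one sample period per class change.

The gradient (drawing direction) is `atan2(−Δy, Δx)` in degrees on
(−180°, 180°]: 0° points rightward and +90° up, because the page's y
axis grows downward (screen convention).  Compass sectors are 45° wide
centered on 0°, ±45°, ±90°, ±135°, 180°; a boundary angle belongs to
the counter-clockwise sector.  Session-average gradient is the
length-weighted circular mean of segment directions, which reduces
exactly to the direction of the summed per-stroke displacement vectors
— this avoids the ±180° wrap-around artifacts an arithmetic mean of
angles would create.

## Parameters and defaults

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| palette | 10 colors (yellow…skin) | — | reference studio setup |
| toolset | 6 tools incl. eraser | — | reference studio setup |
| velocity thresholds (low_max, high_min) | (2, 10) | cm/s | typical session averages of 6–12 cm/s fall in "medium"; the class bounds are not standardized anywhere, so they are configurable and should be reported with results |
| pressure thresholds | (⅓, ⅔) | — | tertiles of the normalized [0,1] range |
| size thresholds (short, long) | (2, 10) | cm | a "short" stroke is a tick mark, a "long" one crosses a good part of a 20 cm page |
| center_fraction | 0.5 | — | the centered rectangle at half the linear page scale |
| raster_cell | 0.25 | cm | area-coverage grid; refine for small tools |
| tool widths | 0.1–0.8 | cm | nominal swept widths per tool (pencil thin, eraser wide) |

Quarter assignment ties (a point exactly on a midline) resolve to the
left/top quarter; the center rectangle is inclusive of its edge.  Both
choices are arbitrary but fixed and shared by every code path.

## Metric accounting conventions

* `drawing_pct` is Painting occupancy over session duration; `idle_pct`
  is its complement (material-selection time is reported on its own
  line but folds into idle for the two-way split).
* Average velocity is total stroke length over total in-stroke time —
  not the mean of per-stroke velocities.
* Eraser strokes are strokes: they count fully in stroke counts,
  lengths and kinematics.  Their time is reported under the
  pseudo-color `"erase"` and excluded from real-color occupancy;
  `colors_used_pct` and the distinct-color count behind
  `switches_per_color` likewise ignore eraser strokes' nominal colors,
  while the switch *counts* run over the raw per-stroke sequences.
* A "horizontal crossover" crosses the *horizontal* midline (movement
  between vertically adjacent quarters); a "vertical" one crosses the
  vertical midline; one sample pair can increment both.  The naming
  follows the pairing of vertical hand movements with horizontal
  midline crossings.
* A stroke-start crossover compares a stroke's first-sample quarter
  with the *previous stroke's last-sample* quarter (where the hand
  last was) and counts edge adjacency only — the diagonal quarter is
  not adjacent.
* Area coverage sweeps a disc of half the tool width along each stroke
  polyline on a square grid; a cell counts when its center is inside
  the sweep.  Eraser strokes count as page activity regardless of what
  they removed.

Two independent computation paths produce the occupancy metrics: the
statechart trace (primary) and a direct pass over strokes and events;
the test suite holds them equal to 1e-9 relative on every fixture and
on random sessions.

## Statistics

Group comparisons follow the two-test convention: a Welch t-test on
means (a pooled-variance switch exists but unequal variances are the
safe default at n = 6 per group) and a two-sided Wilcoxon rank-sum /
Mann-Whitney U on the same values, exact when the combined sample is
≤ 20 without ties, otherwise normal approximation with tie correction.
A metric is flagged only when significant under both tests.  No
multiple-testing correction is applied by default — scans report raw
p-values — with Benjamini–Hochberg q-values available behind a flag as
an extension.  Pooling tasks treats repeated sessions of one subject as
independent observations; this mirrors the n = 36 style of analysis but
is a known caveat (no mixed-effects modeling here).

Calibration: under the null with n = 6/6, the exact rank-sum test's
achievable two-sided size at nominal α = 0.05 is ≈ 0.041 (discreteness
of the U distribution), the Welch test sits near 0.05, and the both-
tests rule can only reject less than either — all verified by seeded
Monte Carlo in the acceptance suite (2000 replicates).

## The synthetic generator

Scripted sessions compose geometric primitives — lines, polylines,
circle arcs, zigzags — drawn at constant speed with constant or
linearly ramping pressure, separated by idle gaps and selection events.
Sample times are a uniform grid at the session rate *plus the control-
vertex passage times* (endpoints always included), so a polyline's
sampled chords sum exactly to its arc length; circle arcs remain
chord-approximated (≈0.1% short at 100 Hz for a 3 cm radius).

Ground truth is computed from the script parameters, never from the
realized event stream.  Time-in-state quantities are evaluated
analytically on the known sampling grid (closed-form positions at the
grid times) because the left-sample-hold convention makes grid-free
geometric clipping differ by O(crossings × sample period); stroke
lengths are reported both ways — exact arc length and grid-chord sum.
Integer quantities (counts, switches, crossovers, start quarters) must
be recovered exactly; continuous ones to ≤ 0.5% at 100 Hz.

Random cohorts draw per-group session parameters: stroke count
Poisson(12), speed log-normal (median 8 cm/s, σ = 0.4 on the log
scale), pressure Normal(0.6, 0.08) clipped to [0.05, 0.95], color
choice Dirichlet-weighted over the palette, eraser propensity 0.15,
and a per-session Beta(2, 2) idle fraction realized through exponential
inter-stroke gaps.  These defaults produce sessions of a few dozen
seconds with roughly half the time idle and velocities in the upper
single digits of cm/s — the regime the method targets — at a size that
keeps 500-session property runs and 1000-replicate power studies
tractable on one CPU.  The power study plants its effect as a group
speed multiplier: scaling every stroke speed by k scales a session's
average velocity by exactly k, so a 2-SD shift in mean avg_velocity is
planted by k = 1 + 2σ/μ with μ, σ estimated from a seeded null run.
Note that `strokes_per_second` is strokes over drawing time, so a speed
plant legitimately moves it too; the "truly null" set in the power
study excludes it.

What the generator does *not* emulate: human handwriting dynamics
(tremor, curvature-speed coupling), pressure-speed correlation,
semantic object structure, device noise or dropped packets (a uniform
sample-time jitter option exists, off by default).  Passing tests
therefore demonstrate correct decoding and statistics on clean,
well-specified input — not robustness to real tablet idiosyncrasies.

## Playback and reports

The canvas renderer stamps a swept disc of the tool width per segment,
in stream order; the eraser paints the page background (destination-out
sweep — no blending fidelity is attempted).  Rendering is deterministic,
and for eraser-free sessions the set of inked pixels grows monotonically
in time.  The visual report reads every band off the statechart trace
(so nothing can be shown that was not tracked), plots pressure and
wrap-aware gradient tracks, shades erase epochs, and inlines canvas
snapshots at stroke-count quartiles by default.  PNG output strips
volatile metadata so identical inputs give identical bytes.  The
textual report prints percentages to one decimal and is parseable back
into the values it prints.

## Known limitations

* Repeated measures are pooled, not modeled (see Statistics).
* The published class thresholds (velocity, pressure, size) are not
  recoverable from any standard; results depend on them and they must
  be reported alongside.
* Occupancy state-times carry the left-hold discretization bias of up
  to one sample period per state change; at 50–100 Hz this is
  negligible against the metrics' own variability.
* The vendor script format of any particular tablet application is not
  parsed; the JSONL session format documented in the README is the
  ingestion contract, and adapters live upstream.
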