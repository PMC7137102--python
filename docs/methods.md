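# Methods

This note records the conventions, numerical choices and known limits of
emkit's data model, file handlers, transforms and test fixtures.

## Image model and element types

Images are dense 4-D arrays `(n, z, y, x)` with x the fastest-varying axis
(the MRC "column" axis); all modules share this layout.  A file item is
either a 2-D stack (`z == 1`, `n ≥ 1`) or a single volume (`n == 1`,
`z > 1`); stacks of volumes are rejected rather than guessed at.  Indices
are 0-based throughout the library; only the CLI accepts the EM-field
1-based `N@stack` convention.

The element-type set is closed — int8, int16, int32, uint8, uint16,
float32, float64 — with a lossless-widening partial order (int8→int16→
int32→float64, uint8→int16, uint16→int32, float32→float64).  Narrowing
casts round half-to-even and clamp to the destination range by default;
an `error-on-overflow` policy raises instead.  Round-clamp is the default
because it matches how EM format converters usually behave; the strict
policy exists for pipelines that must not silently lose range.  Statistics
use the population (divide-by-N) standard deviation, matching the MRC RMS
header field convention.

`Image.item(i)` always returns a copy, never a view.  Cheaper aliasing
semantics were considered and rejected: every processor is out-of-place,
and a copy-always contract removes any possibility of one stage mutating
another's input.

## MRC2014 and SPIDER handlers

Both handlers are written directly against the public format
descriptions; no third-party format library sits behind them.

MRC: 1024-byte header, `MAP ` magic required, machine stamp consulted on
read (`0x44 0x44` little-endian, `0x11 0x11` big-endian; files written are
always little-endian with stamp `0x44 0x44 0x00 0x00` for deterministic
output).  Modes 0 (int8), 1 (int16), 2 (float32) and 6 (uint16) are
supported; complex and packed modes raise.  Element types without a native
mode are widened or round-clamped on write (uint8→mode 6 exactly;
int32/float64→mode 2, refused under the strict policy since the mapping
can lose precision).  Stacks are written `ispg=0, mz=1, nz=n`, volumes
`ispg=1, mz=nz`; on read `ispg=0 ∧ nz>1` means stack.  Pixel size is
`cella/mx`; `cella=0` reads back as *unset*, never as 0.  Header
statistics (dmin/dmax/dmean/rms) are recomputed over the whole file when a
write session closes.  Extended headers (`nsymbt>0`) are preserved
opaquely in `header_meta` on read and never written.

SPIDER: all header values are 32-bit floats; `lenbyt = 4·nsam`,
`labrec = ⌈1024/lenbyt⌉`, `labbyt = labrec·lenbyt`.  Pixel data are
float32 only — any input is cast on write.  Single-image files (iform 1
and 3) are read and written; stack files (`istack>0`) are read-only, since
the splitting workflow only ever needs to *write* individual files.  The
header `scale` slot carries the pixel size when known, 0 otherwise.

Write sessions buffer items in memory and emit the file on close via a
temp-file-plus-rename, so a failed session leaves no partial output.  This
trades peak memory for atomicity, a deliberate choice at the data sizes
this library targets.

## Tables, STAR and delimited text

A table is an ordered list of typed columns (int, float, string, bool)
plus rows; cells may hold an explicit MISSING marker.  The filter grammar
is deliberately minimal — comparisons (`== != < <= > >=`) over columns and
literals combined with `and/or/not` and parentheses, no arithmetic —
because a bounded grammar can be tested exhaustively.  Any comparison
involving MISSING is false, which guarantees that `e` and `not (e)`
partition the rows.  Sorts are stable in both directions; MISSING sorts
last.  Column statistics exclude MISSING and use the population standard
deviation, accumulated with compensated summation.

STAR follows the RELION dialect: `data_` blocks, `loop_` tables with
`_label #N` ordinals (honoured for column order on read, always written),
`.`/`?` read as missing and `.` written, `#` comments, quoted tokens
keeping embedded whitespace, and semicolon-delimited multi-line text
fields read but never written.  Single-row tables serialize as key-value
blocks, multi-row (and empty) tables as loops.  Column types are inferred
deterministically from the token set — int if every token parses as an
integer, else float, else string; quoted tokens force string — so
inference is order-independent.  Floats are written with the shortest
decimal representation that round-trips, and strings that *look* numeric
(or clash with reserved tokens) are quoted, which together make
write→read an involution.  Two deliberate losses: `bool` columns have no
STAR lexical form and are written as 0/1 (read back as int), and an
all-missing or zero-row typed column reads back with inferred (string)
type because no token carries type evidence.

TSV/CSV uses a header row, the same type inference, `.` for missing, and
errors on ragged rows.

## Fourier transforms and rescaling

Conventions are fixed globally: unnormalized forward transform (DC equals
the sum of pixel values), 1/N on the inverse, half-spectrum storage along
x (`x/2 + 1` bins for even x).  Any FFT backend must be wrapped to this
contract; numpy's pocketfft currently provides it.

`spectral_resize` crops (downscale) or zero-pads (upscale) the *centred*
frequency block: the retained frequencies on each resized axis are
`-N'/2 … N'/2-1`, so the new Nyquist bin is taken from the source bin of
frequency `-N'/2`.  Coefficients are scaled by `N'_total/N_total` and the
result is Hermitian-symmetrized (`F ← (F + conj(F[-k]))/2`) so it remains
a valid spectrum of a real image.  This makes the inverse preserve the
real-space mean exactly (the DC bin is real and only rescaled) and makes
the operation reproducible by a direct-DFT oracle with the same index
arithmetic.  Odd target extents are rejected: splitting a Nyquist bin for
odd sizes admits several equally defensible conventions, and refusing is
cheaper than documenting one.

The low-pass processor multiplies the spectrum by a raised-cosine mask:
1 below `cutoff − w`, 0 at and above `cutoff`, half-cosine edge of width
`w` (default 0.02 cycles/pixel) to limit ringing.  Frequency magnitude is
measured with the **max-norm** over per-axis digital frequencies rather
than the Euclidean radius.  With the Euclidean norm the grid corners reach
|f| ≈ 0.707, so a cutoff of 0.5 — the natural "pass everything" setting —
would still erase the corners; under the max-norm every grid frequency is
≤ 0.5 and cutoff 0.5 with zero edge width is exactly the identity.  The
passband is therefore square, which is acceptable for a utility filter
(anti-aliasing before decimation is handled by Fourier cropping itself,
not by this mask).

## Processors and pipelines

All processors validate parameters at construction, never mutate them,
process out-of-place, and apply per item across stacks.  Arithmetic runs
in float64 whatever the input type and casts back with round-clamp, so
integer images saturate instead of wrapping.  The rescale processor
outputs float32 for integer and float32 inputs and keeps float64 inputs
in float64 — the Fourier path is inherently non-integral, but discarding
double precision that the caller supplied would be a gratuitous loss.
Its factor form computes each target extent as `round(extent·factor/2)·2`
(nearest even size), and the pixel size scales inversely with the
geometric change.  Window crop/pad uses a left/top margin of `⌊Δ/2⌋`, so
pad-then-crop is an exact identity.

`PipeProc` executes steps sequentially in insertion order; the empty pipe
is the identity.  A failure at step *k* propagates annotated with *k* and
discards intermediates — no partial results.  Parallel execution is out
of scope; sequential composition is the semantic, parallelism would be an
optimization.

Exact-identity claims for arithmetic inverse pairs (`add a` then
`subtract a`) hold for integer images and for float images whose values
and operand are exactly representable at the working precision; for
arbitrary float64 data `(x + a) − a` is not an identity in IEEE
arithmetic, and tests state the tolerance they use.

## CLI

`em-image` applies its operation flags in command-line order as one pipe,
making composition visible in the invocation itself; `em-table` fixes the
relational order filter → sort → column-select for predictability.  All
outputs are written to a temp file and atomically renamed, and `--split`
renames only after every member file has been written, so error paths
(non-zero exit, one-line stderr diagnostic) never leave partial outputs.

## Fixtures and oracles

All test inputs are generated at run time; nothing is downloaded or
checked in.  Phantom patterns (constant, impulse, checkerboard, centred
Gaussian blob with σ = min(y,x)/6 and peak 1, seeded uniform noise in
[0, 1)) are bit-reproducible from their spec and seed.  Integer-typed
noise phantoms draw seeded integers in [0, 100) instead, since [0, 1)
floats would collapse to zero.

The cross-validation oracles — byte-level MRC and SPIDER writers and
parsers, a minimal STAR reader, and a direct O(N²) DFT (explicit
exponential matrices, capped at 4096 elements to bound runtime) — are
implemented directly from the format and transform definitions and share
no code with the modules they check.  Agreement between the two
independent implementations is the test.

What the synthetic inputs do *not* model: CTF effects, realistic noise
spectra, projection geometry, or vendor extended headers with meaningful
content.  Passing tests therefore demonstrate format and transform
correctness, not robustness to every file wild EM software emits —
notably, MRC files lacking the `MAP ` magic (some pre-2014 writers) are
rejected rather than guessed at.

## Problem sizes

The suite and the acceptance script run on 16×16–64×64 images, 10-item
stacks, ≤50-row tables and 200 randomized STAR documents.  These sizes
exercise every code path (header geometry, stack/volume disambiguation,
multi-record SPIDER headers, quoting and missing-value corners) while
keeping the full run in seconds; correctness here is size-independent
because the handlers contain no size-dependent logic beyond buffer
arithmetic.
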