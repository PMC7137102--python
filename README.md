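# emkit

Building blocks for cryo-EM image and metadata handling: a typed 4-D image
container, byte-exact MRC2014 and SPIDER file handlers, STAR/TSV metadata
tables, and a composable image-processing pipeline, exposed both as a Python
library and as the `em-image` / `em-table` command-line tools.

## Who this is for

Single-particle cryo-EM workflows shuffle the same few artifacts between
programs: micrographs and particle stacks in MRC format, legacy SPIDER
images, and STAR metadata tables (defocus values, particle coordinates,
class assignments).  Most established packages bundle this plumbing deep
inside much larger codebases.  emkit provides just the plumbing, with a
small, explicit API, so that scripts and new tools can read, transform and
write EM data without pulling in a full processing suite.

## Core model

* **Image** — every image is a dense 4-D array with axes `(n, z, y, x)`
  (x fastest, matching the MRC column axis): a 2-D image is `(1, 1, y, x)`,
  a particle stack `(n, 1, y, x)`, a volume `(1, z, y, x)`.  Element types
  form a closed set (int8/16/32, uint8/16, float32/64) with explicit cast
  rules: widening is value-exact, narrowing rounds half-to-even then clamps
  (or raises, under the strict policy).
* **File handlers** — `ImageFile` dispatches on format: MRC2014
  (1024-byte header, `MAP ` magic, machine stamp, modes 0/1/2/6, stacks as
  `ispg=0, mz=1, nz=n`, pixel size `cella/mx`) and SPIDER (all-float header,
  `labbyt = labrec·lenbyt`, float32 data).  Files written are always
  little-endian; reads honour the declared byte order.
* **Table** — ordered typed columns plus rows; filter expressions
  (comparisons combined with `and/or/not`), stable sorts, population
  statistics, and STAR (RELION dialect, `#N` ordinals, `.`/`?` as missing)
  and TSV/CSV backends with deterministic type inference.
* **Processors** — `process(image)` transforms applied out-of-place and
  per item across stacks: scalar arithmetic, centred window crop/pad,
  raised-cosine low-pass, and Fourier-cropping rescale.  Rescaling keeps the
  centred low-frequency block of the DFT — ideal sinc-interpolation
  resampling — with coefficients rescaled so the image mean is preserved
  exactly.  `PipeProc` concatenates processors so chained operations never
  write intermediate files.

## Worked example

```sh
$ em-image particles.mrcs --info
format: mrc
dims (n,z,y,x): 10 x 1 x 16 x 16
dtype: float32
pixel size: 1 A/px

# split a stack into one SPIDER file per particle
$ em-image particles.mrcs --split part_%02d.spi

# invert contrast and Fourier-crop to half size, in one pipe
$ em-image micrograph.mrc --mult -1 --scale 0.5 small.mrc
$ em-image small.mrc --info
format: mrc
dims (n,z,y,x): 1 x 1 x 32 x 32
dtype: float32
pixel size: 2 A/px
```

The 64×64 micrograph at 1 Å/px becomes 32×32 at 2 Å/px: half the pixels,
twice the sampling distance, and (because the rescale preserves the mean
and `--mult -1` negates it) the output mean is exactly minus the input
mean.

```sh
$ em-table micrographs.star --stats defocus
count	4
min	1.2
max	3
mean	2.125
std	0.683283

$ em-table micrographs.star --filter "defocus < 2.0" --sort defocus
id	defocus	name	score
1	1.2	mic_a	0.5
3	1.8	mic c	2.5
```

`--stats` reports the count and population moments of a numeric column;
filtering keeps the two micrographs under 2 µm defocus and prints them as
TSV.  Library-level equivalents of every CLI call exist (`emkit.load`,
`emkit.save`, `Table.filter`, `PipeProc`, ...); the CLI is a thin shell
over them.

Deterministic demo inputs can be materialized with
`em-fixtures <directory>`.

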