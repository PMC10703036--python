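# fpnhse

Decision-support library and CLI for ranking alternatives — typically
patients by disease risk — from multi-expert neutrosophic assessments over
multi-argument attribute tuples, using fuzzy-parameterized neutrosophic
hypersoft expert sets (FpNHse-sets) and a modified Sanchez matrix method.

## Who this is for

Researchers in fuzzy multi-attribute decision making who want a tested,
reproducible implementation of the FpNHse-set data model and its associated
diagnosis pipeline: the packaged heart-disease case study (6 patients,
8 sub-attribute tuples built on Cleveland-dataset attribute ranges,
4 experts) runs out of the box, and a seeded generator produces
structurally identical random cases at any dimensions.

## The method

Each attribute is classified into disjoint sub-attribute values; a parameter
is a tuple with one value per attribute. Experts grade each alternative on
each tuple with a neutrosophic triplet (t, i, f) ∈ [0,1]³ (truth,
indeterminacy, falsity). Each tuple carries a fuzzy parameterized degree

    χ = (μ_max − μ_min) / 2

where μ are the attribute's normalized prescribed values (v / v_max). The
pipeline reduces both assessment matrices elementwise with

    m(t, i, f) = |t − i − f| / 3,

weights the patients×tuples matrix column-wise and the tuples×experts matrix
row-wise by χ, composes them by an ordinary matrix product into a
patients×experts diagnosis matrix D, scores each patient by the row sum of
D, and ranks descending (higher score = higher risk). Arithmetic, geometric
and harmonic means of the diagnosis rows provide a rank-stability check.
See `docs/methods.md` for assumptions, rounding conventions and limitations.

## Worked example

```python
from fpnhse import load_paper_fixture, run_fuzzy_pipeline, sensitivity_report

fx = load_paper_fixture()
result = run_fuzzy_pipeline(fx.fuzzy_patients, fx.fuzzy_experts, fx.chi)
print(" > ".join(result.ranking))
print(result.scores.round(4).to_dict())

report = sensitivity_report(fx.diagnosis, list(fx.ranking))
print(report.means)
```

prints

```
P303 > P24 > P25 > P75 > P2 > P1
{'P1': 0.0602, 'P2': 0.0783, 'P24': 0.1015, 'P25': 0.0897, 'P75': 0.082, 'P303': 0.1447}
          am      gm      hm
P1    0.0189  0.0182  0.0175
P2    0.0196  0.0193  0.0191
P24   0.0254  0.0250  0.0246
P25   0.0225  0.0216  0.0208
P75   0.0205  0.0193  0.0182
P303  0.0327  0.0324  0.0321
```

Patient P303 carries the highest composed risk score and tops the ranking;
the mean-based scores shrink the scale (they average instead of summing the
four expert columns), and the arithmetic- and geometric-mean orderings agree
with the score ranking. Three recomputed scores differ from the case study's
published values (0.0756, 0.0898, 0.1308 for P1, P25, P303): the published
tables contain a handful of arithmetic slips — including a diagnosis cell
and a weighted value carried forward with a misplaced decimal point — that
this end-to-end run corrects. The fixture documents every such cell in its
`ERRATA` list, the ranking is unaffected, and `fpnhse verify-paper`
recomputes the whole case and reports each cell as ok / known erratum /
failure.

## Command line

```
fpnhse simulate --patients 6 --tuples 8 --experts 4 --seed 1 --out case.json
fpnhse diagnose --case case.json --out report.json
fpnhse sensitivity --report report.json
fpnhse verify-paper
fpnhse --rounding full diagnose --case case.json --out report.json
```

`--rounding paper` (default) reproduces the published tables' 2-/4-decimal
half-up rounding; `--rounding full` keeps full precision. Case files are
JSON (schema in `fpnhse.caseio`); single matrices can also be read/written
as CSV with cells serialized `"t;i;f"`.

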