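# iltox

Unified LFER modelling of ionic-liquid (IL) toxicity across many
biological test systems.

Ionic liquids are tunable salts with millions of candidate structures;
testing each one against every ecotoxicological endpoint is infeasible.
`iltox` implements a single pooled prediction framework for IL toxicity:
one linear free energy relationship (LFER) over split cation/anion
solvation descriptors, shared by all test systems, plus a small set of
per-system sensitivity terms. It is aimed at QSAR/ecotoxicology
practitioners who want to screen candidate cation–anion combinations, rank
ions by their toxic contribution, or calibrate a brand-new assay from a
handful of measurements.

## The model

All endpoints (EC50, LC50, IC50, MIC, MBC; C in mM) are pooled on one
response scale, log₁₀(1/C). The pooled regression is

```
log 1/C = e_c E_c + s_c S_c + a_c A_c + b_c B_c + v_c V_c + j⁺ J⁺
        + e_a E_a + s_a S_a + a_a A_a + b_a B_a + v_a V_a + j⁻ J⁻
        + c + Σ_x z_x Z_x
```

with Abraham-type descriptors E (excess molar refraction), S
(dipolarity/polarizability), A/B (H-bond acidity/basicity), V (McGowan
volume) and J⁺/J⁻ (ionic interaction), split into cation (subscript c)
and anion (subscript a) parts; Z_x is a 0/1 indicator per test system and
z_x that system's sensitivity offset (the reference system, the one with
the most data, has z = 0). Insignificant descriptors (p > 0.05) are
removed by backward elimination. Each system additionally gets a linear
calibration `observed ≈ α_x·(intrinsic + z_x) + β_x`, and external
predictions are judged by trimmed-MAE criteria. The published
nine-coefficient model and the 58-system sensitivity catalogue ship with
the package (`iltox.published_model()`, `iltox.published_table()`).

See `docs/methods.md` for assumptions, conventions and limitations.

## Worked example

```python
from iltox import (IonDescriptors, published_model, intrinsic_value,
                   predict_eq4, cation_contribution, anion_contribution)

model = published_model()
# synthetic descriptor values for a butylimidazolium-like cation
# and a chloride-like anion (real descriptor tables are inputs)
cat = IonDescriptors("BMIM", "cation", E=0.30, S=1.60, A=0.25, B=0.10,
                     V=1.25, J=1.10)
an = IonDescriptors("Cl", "anion", E=0.20, S=0.60, A=0.00, B=1.20,
                    V=0.23, J=-0.10)

print(round(intrinsic_value(cat, an, model), 3))              # 1.224
print(round(predict_eq4(cat, an, "D. magna (B & C)", model), 3))  # 2.854
print(round(predict_eq4(cat, an, "V. fischeri (A)", model), 3))   # 1.454
print(round(cation_contribution(cat, model), 3))              # 1.89
print(round(anion_contribution(an, model), 3))                # 0.043
```

The intrinsic value 1.224 is the pair's system-free toxicity in
log₁₀(1/mM): about 0.06 mM at the reference assay's sensitivity. The
water-flea system is 1.63 log units more sensitive (z = 1.63), giving a
predicted immobilisation EC50 near 1.4 µM, while the luminescent-bacteria
assay (z = 0.23) is close to the reference. The cation dominates the toxic
contribution (1.89 vs 0.043 log units), the usual pattern for
imidazolium halides.

The same pipeline is scriptable from the shell:

```bash
iltox show-published                 # coefficients + 58-system catalogue
iltox simulate --seed 7 --out-dir demo/
iltox fit --toxicity demo/toxicity.csv --descriptors demo/descriptors.csv \
      --out demo/model.json
iltox calibrate --model demo/model.json --toxicity demo/toxicity.csv \
      --descriptors demo/descriptors.csv --out demo/calib.json
iltox validate --model demo/model.json --calib demo/calib.json \
      --toxicity demo/toxicity.csv --descriptors demo/descriptors.csv \
      --out demo/report.json
iltox rank --descriptors demo/descriptors.csv --role anion --out demo/rank.csv
```

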