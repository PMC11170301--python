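# erpo-avert

Counterfactual method-substitution modelling of suicide mortality: how many
extreme risk protection orders (ERPOs) must be issued to prevent one
suicide death?

ERPOs are civil court orders that temporarily remove firearms from people
judged to pose a danger to themselves or others. Their individual-level
benefit cannot be observed directly, but it can be modelled: observed
method-specific suicide deaths among ERPO respondents are inverted into
estimated suicidal acts using method-specific case fatality ratios (CFRs),
those acts are redistributed under a counterfactual method mix (what
respondents would have used had their firearms not been removed), and the
counterfactual mortality is reconstructed. The package is for
epidemiologists and policy analysts who want this estimator, its
sensitivity analyses, and its uncertainty, as reproducible code.

## The model

With observed deaths D_m by method m, CFRs p_m, N subjects, and a
counterfactual act distribution q:

    A_m = D_m / p_m                     estimated suicidal acts (step 1)
    A   = Σ_m A_m
    D*  = A · Σ_m q_m p_m               counterfactual deaths (steps 2–3)

    deaths averted  = D* − D
    risk difference = (D* − D) / N
    NNT             = N / (D* − D)

Act conservation — the intervention changes the method mix of acts, not
their number — is the identifying assumption; see `docs/methods.md` for
the full account, including the fixed-firearm-fraction counterfactual and
the parametric bootstrap.

## Worked example

The Connecticut ERPO inputs (21 suicide deaths among 762 respondents,
male CFR table, male handgun-owner act distribution as the counterfactual)
are packaged:

```
$ erpo-avert counterfactual --preset connecticut
```

prints the per-method derivation table and then

```
subjects (N):            762
estimated total acts:    187.3
observed deaths:         21
counterfactual deaths:   55.2
deaths averted:          34.2
risk difference:         4.5 percentage points
NNT:                     22.3
```

Reading: the 21 observed deaths imply ≈187 suicidal acts (most by low-
lethality methods — 2 drug-poisoning deaths alone imply 80 acts at CFR
0.025). Had 28% of those acts involved firearms (CFR 0.904) instead of the
observed 3.5%, ≈55 deaths would have occurred; the ≈34 excess deaths over
762 respondents give one suicide prevented per ≈22 orders issued.

The same pipeline from Python:

```python
import erpo_avert as ea

result = ea.run_counterfactual(ea.connecticut_scenario())
print(round(result.total_acts, 1))                  # 187.3
print(round(result.counterfactual_total_deaths, 1)) # 55.2
print(round(result.nnt, 1))                         # 22.3
```

Other subcommands: `acts` (CFR inversion alone), `sweep` (NNT vs the
counterfactual firearm fraction), `tabulate` (cohort CSVs into mortality
and act distributions by ownership × sex), `simulate` (synthetic cohorts
and forward act/death simulation), `bootstrap` (percentile intervals).

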