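# Published input tables (not redistributed)

The worked-example acceptance test runs the attribution chain from the
source study's published supplementary tables.  Those tables are not
redistributable with this package; to run the worked example, place them
here as plain CSV:

* `table_a2_prevalence.csv` — modelled weighted proportions of the 32
  maltreatment patterns, columns
  `gender,age_group,pattern,proportion[,effective_n]` with `pattern` the
  5-character PA/SA/EA/N/EDV code (e.g. `10110`) and one full 32-pattern
  distribution per gender × age-group stratum.
* `table1_rr.csv` — simply adjusted relative risks, columns
  `outcome,gender,coding,level,rr,lcl,ucl` with outcome in
  {mdd,gad,ptsd,aud,smoking,suicide_attempt}, coding `count_of_types`,
  level `0`–`5`.
* `gbd2021_burden.csv` (optional, enables the all-DALY-share check) —
  columns `cause,gender,age_group,deaths,yll,yld,daly[,burden_type]` with
  causes {mdd,anxiety_total,self_harm,aud,smoking_attributable,all_causes};
  the smoking row must be smoking-attributable burden flagged
  `burden_type=attributable`.

Age groups are `15–19`, `20–24`, …, `80+` (ASCII hyphens accepted).
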