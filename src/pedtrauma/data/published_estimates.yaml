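# Published national survey estimates for US pediatric (0-19 y) pedestrian and
# bicyclist motor-vehicle-related ED discharges, 2006-2012 (NEDS-based study).
# Point estimates with standard errors (annual table) or 95% CI bounds (TBI
# table). These are reference INPUTS for in-source arithmetic checks and
# worked examples; the package never fits to them.

annual:
  # year: {mechanism: [estimate, SE]}
  2006: {ped_injuries: [52961, 523], bike_injuries: [18547, 306], both_injuries: [71501, 606],
         ped_deaths: [515, 52], bike_deaths: [85, 21], both_deaths: [600, 56]}
  2007: {ped_injuries: [53577, 516], bike_injuries: [19093, 306], both_injuries: [72661, 600],
         ped_deaths: [463, 53], bike_deaths: [72, 18], both_deaths: [536, 56]}
  2008: {ped_injuries: [52417, 503], bike_injuries: [19326, 306], both_injuries: [71729, 589],
         ped_deaths: [511, 51], bike_deaths: [92, 21], both_deaths: [603, 55]}
  2009: {ped_injuries: [47074, 487], bike_injuries: [17654, 301], both_injuries: [64714, 572],
         ped_deaths: [426, 45], bike_deaths: [70, 20], both_deaths: [496, 50]}
  2010: {ped_injuries: [46268, 485], bike_injuries: [18055, 304], both_injuries: [64307, 572],
         ped_deaths: [410, 44], bike_deaths: [58, 20], both_deaths: [468, 48]}
  2011: {ped_injuries: [44647, 465], bike_injuries: [16724, 283], both_injuries: [61371, 544],
         ped_deaths: [332, 41], bike_deaths: [48, 15], both_deaths: [380, 44]}
  2012: {ped_injuries: [42839, 452], bike_injuries: [17982, 299], both_injuries: [60811, 542],
         ped_deaths: [386, 44], bike_deaths: [63, 19], both_deaths: [449, 48]}

totals:
  ped_injuries: [339783, 1298]
  bike_injuries: [127379, 796]
  both_injuries: [467093, 1522]
  ped_deaths: [3042, 125]
  bike_deaths: [488, 51]
  both_deaths: [3531, 135]

period:
  total_ed_discharges_0_19: 217551676
  total_pediatric_ed_deaths: 101147
  severe_rate_all_per_10k: 104.2      # severely injured (ICISS<0.94) per 10^4 ED discharges, all causes
  severe_rate_cohort_per_10k: 920.0   # same rate among pedestrian/bicyclist discharges
  cfr_2006_per_10k: 83.7              # cohort case fatality per 10^4 visits
  cfr_2012_per_10k: 73.7

# Injuries / deaths / case fatality with a primary TBI diagnosis, by Barell grade
tbi_grades:
  type1: {injuries: [6690, 6205, 7175], deaths: [885, 553, 1217], cfr_pct: 13.2}
  type2: {injuries: [17290, 16037, 18543], deaths: [60, 38, 83], cfr_pct: 0.3}
  type3: {injuries: [1670, 1549, 1800], deaths: null, cfr_pct: null}

# Stratum fatality risks for the additive-interaction contrast between
# pedestrian status and primary TBI (per-discharge risk scale as published).
interaction_risks:
  ped_tbi: 4466.5
  ped_notbi: 268.1
  bike_tbi: 1968.3
  bike_notbi: 79.9
bootstrap_ap_pct: [49.1, 38.4, 59.4]
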