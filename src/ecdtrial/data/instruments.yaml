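# Instrument dictionaries: item ids, legal codes, subscale membership.
# Version: 1. Edit with care — scoring validates responses against this registry.
version: 1

fci:
  # Family Care Indicators. Activities: stimulating caregiving activities in the
  # previous 3 days (caregiver report). Materials: varieties of play materials
  # observed in the home. Observation: caregiver responsiveness and home
  # environment items recorded during the interview.
  codes: [0, 1]
  subscales:
    activities:
      - fci_act_read
      - fci_act_told_stories
      - fci_act_sang
      - fci_act_took_outside
      - fci_act_played
      - fci_act_named_drew
    materials:
      - fci_mat_music
      - fci_mat_drawing
      - fci_mat_pretending
      - fci_mat_movement
      - fci_mat_shapes
      - fci_mat_stacking
    observation:
      - fci_obs_01
      - fci_obs_02
      - fci_obs_03
      - fci_obs_04
      - fci_obs_05
      - fci_obs_06
      - fci_obs_07
      - fci_obs_08
      - fci_obs_09
      - fci_obs_10
      - fci_obs_11

asqi:
  # Milestone inventory; per-item response is a 3-level category. The default
  # numeric scheme follows the ASQ convention (yes=10, sometimes=5, not yet=0).
  codes: ["yes", "sometimes", "not_yet"]
  scheme:
    "yes": 10
    sometimes: 5
    not_yet: 0
  domains: [communication, gross_motor, fine_motor, problem_solving, personal_social]
  items_per_domain: 6

cesd:
  # 20-item depressive-symptom scale, each item scored 0-3 by frequency.
  # reverse_items (1-based positions 4, 8, 12, 16) are the positively worded
  # items of the standard key and are reverse-coded before summing.
  codes: [0, 1, 2, 3]
  items:
    [cesd_01, cesd_02, cesd_03, cesd_04, cesd_05, cesd_06, cesd_07, cesd_08,
     cesd_09, cesd_10, cesd_11, cesd_12, cesd_13, cesd_14, cesd_15, cesd_16,
     cesd_17, cesd_18, cesd_19, cesd_20]
  reverse_items: [cesd_04, cesd_08, cesd_12, cesd_16]

diet:
  # Minimum dietary diversity food-group lists. Women: at least 5 of 10 groups
  # consumed in the previous 24 h. Children (over 6 months): at least 5 of 8
  # groups, counting breastmilk as a group.
  maternal_groups:
    - grains_roots_tubers
    - legumes
    - nuts_seeds
    - dairy
    - flesh_foods
    - eggs
    - dark_green_leafy
    - other_vitamin_a
    - other_vegetables
    - other_fruits
  child_groups:
    - breastmilk
    - grains_roots_tubers
    - legumes_nuts
    - dairy
    - flesh_foods
    - eggs
    - vitamin_a_fruit_veg
    - other_fruit_veg
  maternal_threshold: 5
  child_threshold: 5
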