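# Default contact archetypes for the 18 office activities, on the 20x10
# sensor grid (rows run along the arm, columns around it).  Each blob is
# [center_row, center_col, row_sd, col_sd, peak_amplitude] in grid units /
# 12-bit ADC counts; an activity's image is the clipped sum of its blobs,
# truncated to zero below the configured support floor so patches stay
# compact like real contact prints.  Layouts are stylized: unimodal or
# bimodal patches at the places an arm touches a desk, wall, baffle or
# body part during that activity.
activities:
  stand:
    - [10.0, 2.0, 2.4, 0.9, 600]
  fold_arms:
    - [6.0, 4.5, 1.2, 1.2, 1800]
    - [14.0, 5.0, 1.5, 1.2, 1400]
  think:
    - [16.5, 5.0, 1.2, 1.5, 3200]
  side_against_wall:
    - [9.0, 8.0, 3.0, 0.7, 2200]
  back_against_wall:
    - [4.0, 5.0, 1.5, 1.5, 2000]
  arm_on_baffle:
    - [10.0, 4.5, 0.7, 1.8, 3000]
  hug_doll:
    - [8.0, 5.0, 2.7, 1.8, 1500]
  carry_box:
    - [5.0, 3.0, 1.2, 0.9, 2600]
    - [15.0, 6.5, 1.2, 0.9, 2600]
  lean_forward_at_work:
    - [13.0, 4.0, 2.4, 1.3, 2800]
  lean_back_at_work:
    - [17.0, 6.0, 1.1, 1.1, 2400]
  sleep_on_table:
    - [9.0, 5.0, 3.6, 1.9, 2900]
  hold_cheeks:
    - [18.0, 3.5, 0.9, 0.9, 2700]
  play_mobile_phone:
    - [16.0, 2.5, 1.0, 0.7, 1200]
  write_hunchback:
    - [12.0, 3.0, 2.1, 0.9, 2500]
    - [17.0, 7.0, 0.7, 0.7, 900]
  write_straight_back:
    - [11.0, 6.5, 1.8, 0.85, 2100]
  hands_on_armrests:
    - [9.5, 2.0, 1.7, 0.8, 1900]
    - [9.5, 7.5, 1.7, 0.8, 1900]
  sit_leaning_right:
    - [12.0, 8.5, 2.1, 0.6, 2300]
  arms_on_legs:
    - [7.0, 3.5, 1.3, 1.1, 1600]
    - [13.5, 3.5, 1.3, 1.1, 1600]
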