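# Shipped index catalog: the five composite indexes used to benchmark the
# 21 Italian regions / autonomous provinces, with per-indicator polarity.
# Negative polarity means "more is worse" for the measured phenomenon; such
# columns are reversed (complement w.r.t. 200 of the normalized value)
# before aggregation.
indexes:
  - name: accessibility
    display: Accessibility
    indicators:
      - key: family_health_expenditure_eur
        display: "Family health expenditure (Eur)"
        polarity: negative
        source: HFA
        year: "2014"
      - key: pct_cervical_cancer_screening
        display: "% Cervical cancer screening"
        polarity: positive
        source: PASSI
        year: "2013-2015"
      - key: pct_breast_cancer_screening
        display: "% Breast cancer screening"
        polarity: positive
        source: PASSI
        year: "2010-2013"
      - key: residential_beds_per_inhabitant
        display: "No. residential social-health residential beds for the elderly and people with disabilities (for inhabitant)"
        polarity: positive
        source: "Osserva Salute"
        year: "2013"
  - name: quality
    display: Quality
    children:
      - name: effectiveness
        display: Effectiveness
        indicators:
          - key: net_survival_5y_neoplasia
            display: "5 years net survival rate after diagnosis of neoplasia (all locations except total skin)"
            polarity: positive
            source: PASSI
            year: "2015"
          - key: suicide_mortality_rate
            display: "Suicide mortality rate, self-injury"
            polarity: negative
            source: HFA
            year: "2015"
      - name: safety
        display: Safety
        indicators:
          - key: pct_caesarean_sections
            display: "% Caesarean sections"
            polarity: negative
            source: "SDO Report"
            year: "2017"
          - key: sepsis_mortality_rate_75plus
            display: "Standardised rate (per 10,000 people) of sepsis-related mortality in the population of 75+"
            polarity: negative
            source: "Osserva Salute"
            year: "2016"
          - key: pct_short_hospital_stays
            display: "% Short hospital stays (2-3 days) out of total medical DRGs"
            polarity: negative
            source: "SDO Report"
            year: "2017"
      - name: responsiveness
        display: Responsiveness/Patient-centeredness
        indicators:
          - key: pct_very_satisfied_medical_care
            display: "% Very satisfied people for hospital medical care"
            polarity: positive
            source: HFA
            year: "2015"
          - key: pct_very_satisfied_hospital_toilets
            display: "% Very satisfied people in hospital toilets"
            polarity: positive
            source: HFA
            year: "2015"
          - key: pct_very_satisfied_nursing_care
            display: "% Very satisfied people hospital nursing care"
            polarity: positive
            source: HFA
            year: "2015"
  - name: cost_expenditure
    display: Cost/expenditure
    indicators:
      - key: public_health_expenditure_per_capita
        display: "Current public health expenditure per capita"
        polarity: positive
        source: HFA
        year: "2013"
      - key: pct_public_expenditure_of_total
        display: "Public expenditure as a % of total expenditure"
        polarity: positive
        source: HFA
        year: "2013"
      - key: pharmaceutical_expenditure_per_capita
        display: "Gross territorial pharmaceutical expenditure per capita charged to the National Health Service"
        polarity: positive
        source: "Osserva Salute"
        year: "2012"
  - name: health_status
    display: Health status
    indicators:
      - key: life_expectancy
        display: "Life expectancy"
        polarity: positive
        source: HFA
        year: "2015"
      - key: healthy_life_expectancy
        display: "Healthy Life Expectancy"
        polarity: positive
        source: HFA
        year: "2013"
      - key: infant_mortality_rate
        display: "Infant Mortality rate"
        polarity: negative
        source: HFA
        year: "2015"
      - key: physical_status_index
        display: "Physical Status Index"
        polarity: positive
        source: HFA
        year: "2013"
      - key: psychological_status_index
        display: "Psychological Status Index"
        polarity: positive
        source: HFA
        year: "2013"
  - name: lifestyles
    display: Lifestyles
    indicators:
      - key: pct_obese_18plus
        display: "% Obese People 18+"
        polarity: negative
        source: HFA
        year: "2015"
      - key: pct_overweight_18plus
        display: "% People Overweight 18+"
        polarity: negative
        source: HFA
        year: "2015"
      - key: pct_smokers_15plus
        display: "% Smokers 15+"
        polarity: negative
        source: HFA
        year: "2015"
      - key: pct_heavy_smokers_15plus
        display: "% Large Smokers 15+"
        polarity: negative
        source: HFA
        year: "2015"
      - key: avg_cigarettes_daily_15plus
        display: "Average no. of cigarettes daily 15+"
        polarity: negative
        source: HFA
        year: "2015"
      - key: pct_adequate_breakfast_3plus
        display: "% people eating an adequate breakfast 3+"
        polarity: positive
        source: HFA
        year: "2015"
      - key: pct_no_physical_activity_3plus
        display: "% persons not engaged in sport or physical activity 3+"
        polarity: negative
        source: HFA
        year: "2015"
      - key: pct_daily_fruit_vegetables_3plus
        display: "% people consuming fruit or vegetables at least once a day 3+"
        polarity: positive
        source: HFA
        year: "2015"
      - key: hiv_rate
        display: "HIV rate"
        polarity: negative
        source: HFA
        year: "2015"
      - key: pct_hard_drink_predominant
        display: "% persons for whom the predominant drink is a hard drink"
        polarity: negative
        source: HFA
        year: "2015"
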