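[
  {
    "name": "enright_sherrill_1998",
    "citation": "Enright PL, Sherrill DL. Reference equations for the six-minute walk in healthy adults. Am J Respir Crit Care Med. 1998;158:1384-1387.",
    "population": "Healthy US adults, 40-80 y",
    "age_range": [40, 80],
    "male": {"intercept": -309.0, "terms": {"height_cm": 7.57, "mass_kg": -1.76, "age_years": -5.02}},
    "female": {"intercept": 667.0, "terms": {"height_cm": 2.11, "mass_kg": -2.29, "age_years": -5.78}},
    "provenance": "Transcribed from the source publication."
  },
  {
    "name": "troosters_1999",
    "citation": "Troosters T, Gosselink R, Decramer M. Six minute walking distance in healthy elderly subjects. Eur Respir J. 1999;14:270-274.",
    "population": "Healthy Belgian adults, 50-85 y",
    "age_range": [50, 85],
    "male": {"intercept": 269.31, "terms": {"height_cm": 5.14, "age_years": -5.32, "mass_kg": -1.8}},
    "female": {"intercept": 218.0, "terms": {"height_cm": 5.14, "age_years": -5.32, "mass_kg": -1.8}},
    "provenance": "Transcribed from the source publication; sex dummy (+51.31 m for men) folded into the male intercept."
  },
  {
    "name": "gibbons_2001",
    "citation": "Gibbons WJ, Fruchter N, Sloan S, Levy RD. Reference values for a multiple repetition 6-minute walk test in healthy adults older than 20 years. J Cardiopulm Rehabil. 2001;21:87-93.",
    "population": "Healthy Canadian adults, 20-80 y",
    "age_range": [20, 80],
    "male": {"intercept": 868.8, "terms": {"age_years": -2.99}},
    "female": {"intercept": 794.1, "terms": {"age_years": -2.99}},
    "provenance": "Transcribed from the source publication; sex dummy (-74.7 m for women) folded into the female intercept."
  },
  {
    "name": "enright_2003",
    "citation": "Enright PL, McBurnie MA, Bittner V, et al. The 6-min walk test: a quick measure of functional status in elderly adults. Chest. 2003;123:387-398.",
    "population": "Community-dwelling US adults, >=68 y (Cardiovascular Health Study)",
    "age_range": [68, 95],
    "male": {"intercept": 510.0, "terms": {"height_cm": 2.2, "mass_kg": -0.93, "age_years": -5.3}},
    "female": {"intercept": 493.0, "terms": {"height_cm": 2.2, "mass_kg": -0.93, "age_years": -5.3}},
    "provenance": "Transcribed from the source publication."
  },
  {
    "name": "camarri_2006",
    "citation": "Camarri B, Eastwood PR, Cecins NM, Thompson PJ, Jenkins S. Six minute walk distance in healthy subjects aged 55-75 years. Respir Med. 2006;100:658-665.",
    "population": "Healthy Australian adults, 55-75 y",
    "age_range": [55, 75],
    "male": {"intercept": 216.9, "terms": {"height_cm": 4.12, "mass_kg": -1.75, "age_years": -1.14}},
    "female": {"intercept": 216.9, "terms": {"height_cm": 4.12, "mass_kg": -1.75, "age_years": -1.14}},
    "provenance": "UNVERIFIED transcription: coefficients not re-checked against the original publication; structure (anthropometric-only model) follows the source."
  },
  {
    "name": "masmoudi_2008",
    "citation": "Masmoudi K, Aouicha MS, Fki H, Dammak J, Zouari N. [The six minute walk test: which predictive values to apply for Tunisian subjects aged between 40 and 80 years?]. Tunis Med. 2008;86:20-26.",
    "population": "Healthy Tunisian adults, 40-80 y",
    "age_range": [40, 80],
    "male": {"intercept": 385.0, "terms": {"height_cm": 3.0, "mass_kg": -1.5, "age_years": -3.5}},
    "female": {"intercept": 355.0, "terms": {"height_cm": 3.0, "mass_kg": -1.5, "age_years": -3.5}},
    "provenance": "UNVERIFIED placeholder coefficients with the source's covariate structure; replace with values transcribed from the original publication before substantive use."
  },
  {
    "name": "alameri_2009",
    "citation": "Alameri H, Al-Majed S, Al-Howaikan A. Six-min walk test in a healthy adult Arab population. Respir Med. 2009;103:1041-1046.",
    "population": "Healthy Saudi adults",
    "age_range": [16, 50],
    "male": {"intercept": 617.0, "terms": {"age_years": -1.7}},
    "female": {"intercept": 580.0, "terms": {"age_years": -1.5}},
    "provenance": "UNVERIFIED placeholder coefficients with the source's covariate structure; replace with values transcribed from the original publication before substantive use."
  },
  {
    "name": "ben_saad_2009",
    "citation": "Ben Saad H, Prefaut C, Tabka Z, et al. 6-minute walk distance in healthy North Africans older than 40 years: influence of parity. Respir Med. 2009;103:74-84.",
    "population": "Healthy Tunisian adults, >=40 y",
    "age_range": [40, 80],
    "male": {"intercept": 720.5, "terms": {"height_cm": 2.7189, "mass_kg": -2.23, "age_years": -5.14}},
    "female": {"intercept": 560.23, "terms": {"height_cm": 2.7189, "mass_kg": -2.23, "age_years": -5.14}},
    "provenance": "UNVERIFIED transcription (height converted from metres to cm; sex term folded into the female intercept); re-check against the original publication before substantive use."
  },
  {
    "name": "iwama_2009",
    "citation": "Iwama AM, Andrade GN, Shima P, Tanni SE, Godoy I, Dourado VZ. The six-minute walk test and body weight-walk distance product in healthy Brazilian subjects. Braz J Med Biol Res. 2009;42:1080-1085.",
    "population": "Healthy Brazilian adults, 13-84 y",
    "age_range": [13, 84],
    "male": {"intercept": 683.964, "terms": {"age_years": -1.846}},
    "female": {"intercept": 622.461, "terms": {"age_years": -1.846}},
    "provenance": "Transcribed from the source publication; sex dummy (+61.503 m for men) folded into the male intercept."
  },
  {
    "name": "jenkins_2009",
    "citation": "Jenkins S, Cecins N, Camarri B, Williams C, Thompson P, Eastwood P. Regression equations to predict 6-minute walk distance in middle-aged and elderly adults. Physiother Theory Pract. 2009;25:516-522.",
    "population": "Healthy Australian adults, 45-85 y",
    "age_range": [45, 85],
    "male": {"intercept": 867.0, "terms": {"age_years": -5.71, "height_cm": 1.03}},
    "female": {"intercept": 316.0, "terms": {"age_years": -2.86, "height_cm": 2.71}},
    "provenance": "UNVERIFIED transcription (female formula uncertain); re-check against the original publication before substantive use."
  }
]
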