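concept_id,concept_name,domain_id,vocabulary_id,concept_class_id,standard_concept,concept_code,valid_start_date,valid_end_date,invalid_reason
8507,MALE,Gender,Gender,Gender,S,M,1970-01-01,2099-12-31,
8532,FEMALE,Gender,Gender,Gender,S,F,1970-01-01,2099-12-31,
8551,UNKNOWN,Gender,Gender,Gender,S,U,1970-01-01,2099-12-31,
3042931,PHQ-9 item 1,Observation,LOINC,Clinical Observation,S,44250-9,1970-01-01,2099-12-31,
3042932,PHQ-9 item 2,Observation,LOINC,Clinical Observation,S,44255-8,1970-01-01,2099-12-31,
3042933,PHQ-9 item 3,Observation,LOINC,Clinical Observation,S,44259-0,1970-01-01,2099-12-31,
3042934,PHQ-9 item 4,Observation,LOINC,Clinical Observation,S,44254-1,1970-01-01,2099-12-31,
3042935,PHQ-9 item 5,Observation,LOINC,Clinical Observation,S,44251-7,1970-01-01,2099-12-31,
3042936,PHQ-9 item 6,Observation,LOINC,Clinical Observation,S,44258-2,1970-01-01,2099-12-31,
3042937,PHQ-9 item 7,Observation,LOINC,Clinical Observation,S,44252-5,1970-01-01,2099-12-31,
3042938,PHQ-9 item 8,Observation,LOINC,Clinical Observation,S,44253-3,1970-01-01,2099-12-31,
3042939,PHQ-9 item 9,Observation,LOINC,Clinical Observation,S,44260-8,1970-01-01,2099-12-31,
3045301,GAD-7 item 1,Observation,LOINC,Clinical Observation,S,69725-0,1970-01-01,2099-12-31,
3045302,GAD-7 item 2,Observation,LOINC,Clinical Observation,S,68509-9,1970-01-01,2099-12-31,
3045303,GAD-7 item 3,Observation,LOINC,Clinical Observation,S,69733-4,1970-01-01,2099-12-31,
3045304,GAD-7 item 4,Observation,LOINC,Clinical Observation,S,69734-2,1970-01-01,2099-12-31,
3045305,GAD-7 item 5,Observation,LOINC,Clinical Observation,S,69735-9,1970-01-01,2099-12-31,
3045306,GAD-7 item 6,Observation,LOINC,Clinical Observation,S,69689-8,1970-01-01,2099-12-31,
3045307,GAD-7 item 7,Observation,LOINC,Clinical Observation,S,69736-7,1970-01-01,2099-12-31,
45879900,Not at all,Meas Value,LOINC,Answer,S,LA6568-5,1970-01-01,2099-12-31,
45879901,Several days,Meas Value,LOINC,Answer,S,LA6569-3,1970-01-01,2099-12-31,
45879902,More than half the days,Meas Value,LOINC,Answer,S,LA6570-1,1970-01-01,2099-12-31,
45879903,Nearly every day,Meas Value,LOINC,Answer,S,LA6571-9,1970-01-01,2099-12-31,
3042950,PHQ-9 total score,Measurement,LOINC,Clinical Observation,S,44261-6,1970-01-01,2099-12-31,
3045310,GAD-7 total score,Measurement,LOINC,Clinical Observation,S,70274-6,1970-01-01,2099-12-31,
440383,Depressive disorder,Condition,SNOMED,Clinical Finding,S,35489007,1970-01-01,2099-12-31,
442077,Anxiety disorder,Condition,SNOMED,Clinical Finding,S,48694002,1970-01-01,2099-12-31,
436073,Psychotic disorder,Condition,SNOMED,Clinical Finding,S,69322001,1970-01-01,2099-12-31,
4152283,Depressed mood,Condition,SNOMED,Clinical Finding,S,366979004,1970-01-01,2099-12-31,
4053609,Marital status,Observation,SNOMED,Clinical Finding,S,125680007,1970-01-01,2099-12-31,
4033247,Occupation,Observation,SNOMED,Clinical Finding,S,14679004,1970-01-01,2099-12-31,
3058201,EPDS item 1,Observation,LOINC,Clinical Observation,S,99046-1,1970-01-01,2099-12-31,
3058202,EPDS item 2,Observation,LOINC,Clinical Observation,S,99046-2,1970-01-01,2099-12-31,
3058203,EPDS item 3,Observation,LOINC,Clinical Observation,S,99046-3,1970-01-01,2099-12-31,
3058204,EPDS item 4,Observation,LOINC,Clinical Observation,S,99046-4,1970-01-01,2099-12-31,
3058205,EPDS item 5,Observation,LOINC,Clinical Observation,S,99046-5,1970-01-01,2099-12-31,
3058206,EPDS item 6,Observation,LOINC,Clinical Observation,S,99046-6,1970-01-01,2099-12-31,
3058207,EPDS item 7,Observation,LOINC,Clinical Observation,S,99046-7,1970-01-01,2099-12-31,
3058208,EPDS item 8,Observation,LOINC,Clinical Observation,S,99046-8,1970-01-01,2099-12-31,
3058209,EPDS item 9,Observation,LOINC,Clinical Observation,S,99046-9,1970-01-01,2099-12-31,
3059401,CES-D item 1,Observation,LOINC,Clinical Observation,S,89204-1,1970-01-01,2099-12-31,
3059402,CES-D item 2,Observation,LOINC,Clinical Observation,S,89204-2,1970-01-01,2099-12-31,
3059403,CES-D item 3,Observation,LOINC,Clinical Observation,S,89204-3,1970-01-01,2099-12-31,
3059404,CES-D item 4,Observation,LOINC,Clinical Observation,S,89204-4,1970-01-01,2099-12-31,
3059405,CES-D item 5,Observation,LOINC,Clinical Observation,S,89204-5,1970-01-01,2099-12-31,
3059406,CES-D item 6,Observation,LOINC,Clinical Observation,S,89204-6,1970-01-01,2099-12-31,
3059407,CES-D item 7,Observation,LOINC,Clinical Observation,S,89204-7,1970-01-01,2099-12-31,
3059408,CES-D item 8,Observation,LOINC,Clinical Observation,S,89204-8,1970-01-01,2099-12-31,
3059409,CES-D item 9,Observation,LOINC,Clinical Observation,S,89204-9,1970-01-01,2099-12-31,
3059410,CES-D item 10,Observation,LOINC,Clinical Observation,S,89204-10,1970-01-01,2099-12-31,
3059411,CES-D item 11,Observation,LOINC,Clinical Observation,S,89204-11,1970-01-01,2099-12-31,
3059412,CES-D item 12,Observation,LOINC,Clinical Observation,S,89204-12,1970-01-01,2099-12-31,
3059413,CES-D item 13,Observation,LOINC,Clinical Observation,S,89204-13,1970-01-01,2099-12-31,
3059414,CES-D item 14,Observation,LOINC,Clinical Observation,S,89204-14,1970-01-01,2099-12-31,
3059415,CES-D item 15,Observation,LOINC,Clinical Observation,S,89204-15,1970-01-01,2099-12-31,
3059416,CES-D item 16,Observation,LOINC,Clinical Observation,S,89204-16,1970-01-01,2099-12-31,
3059417,CES-D item 17,Observation,LOINC,Clinical Observation,S,89204-17,1970-01-01,2099-12-31,
3059418,CES-D item 18,Observation,LOINC,Clinical Observation,S,89204-18,1970-01-01,2099-12-31,
3059419,CES-D item 19,Observation,LOINC,Clinical Observation,S,89204-19,1970-01-01,2099-12-31,
3059420,CES-D item 20,Observation,LOINC,Clinical Observation,S,89204-20,1970-01-01,2099-12-31,
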