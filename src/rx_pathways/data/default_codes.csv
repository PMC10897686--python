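code,name,category,agent_class,min_daily_dose,code_system
AD-CIT,citalopram,antidepressant,,20,
AD-SER,sertraline,antidepressant,,50,
AD-FLU,fluoxetine,antidepressant,,20,
AD-MIR,mirtazapine,antidepressant,,15,
AD-VEN,venlafaxine,antidepressant,,75,
AD-PAR,paroxetine,antidepressant,,20,
AD-ESC,escitalopram,antidepressant,,10,
AD-DUL,duloxetine,antidepressant,,60,
AD-AMI,amitriptyline,antidepressant,,75,
AD-TRA,trazodone,antidepressant,,150,
AD-NOR,nortriptyline,antidepressant,,75,
AD-VOR,vortioxetine,antidepressant,,10,
AG-LIT,lithium,augmentation_agent,lithium,400,
AG-QUE,quetiapine,augmentation_agent,antipsychotic,150,
AG-OLA,olanzapine,augmentation_agent,antipsychotic,5,
AG-ARI,aripiprazole,augmentation_agent,antipsychotic,2,
AG-RIS,risperidone,augmentation_agent,antipsychotic,1,
AG-THY,levothyroxine,augmentation_agent,thyroxine,25,
AG-T3,liothyronine,augmentation_agent,tri_iodothyronine,20,
AG-LAM,lamotrigine,augmentation_agent,anticonvulsant,100,
AG-VAL,valproate,augmentation_agent,anticonvulsant,500,
OT-PCM,paracetamol,other,,,
OT-OME,omeprazole,other,,,
DEP01,depressive episode,depression,,,read_v2
DEP02,recurrent depression,depression,,,read_v2
F32,depressive episode,depression,,,icd10
F33,recurrent depressive disorder,depression,,,icd10
EXC-BIP,bipolar affective disorder,exclusion,,,read_v2
EXC-DEM,dementia,exclusion,,,read_v2
EXC-MAN,mania,exclusion,,,read_v2
EXC-PSY,psychosis,exclusion,,,read_v2
F20,schizophrenia,exclusion,,,icd10
F25,schizoaffective disorder,exclusion,,,icd10
CMB-ANX,anxiety disorder,comorbidity,,,read_v2
CMB-AST,asthma,comorbidity,,,read_v2
CMB-ALC,alcohol or substance misuse,comorbidity,,,read_v2
CMB-DIA,diabetes mellitus,comorbidity,,,read_v2
SUI-ID,suicidal ideation,suicidality,,,read_v2
SUI-AT,suicide attempt,suicidality,,,read_v2
SUI-SH,self-harm,suicidality,,,read_v2
MHS-REF,referral to mental health services,mhs_referral,,,read_v2
MHS-CON,mental health service contact,mhs_contact,,,read_v2
MHS-AE,emergency department mental health attendance,mhs_contact,,,read_v2
ASS-PHQ,PHQ-9 assessment,assessment,,,read_v2
ASS-GAD,GAD-7 assessment,assessment,,,read_v2
ASS-AUD,AUDIT-C assessment,assessment,,,read_v2
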