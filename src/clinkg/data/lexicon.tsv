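sem_type	canonical	english	variants
disease	直肠腺癌	rectal adenocarcinoma
disease	胃癌	gastric cancer
disease	结肠癌	colon cancer
disease	食管癌	esophageal cancer
disease	胃溃疡	gastric ulcer
disease	十二指肠溃疡	duodenal ulcer
disease	肝硬化	liver cirrhosis
disease	胆囊炎	cholecystitis
disease	胃原发性恶性肿瘤	primary malignant neoplasm of stomach
disease	胃体原发性恶性肿瘤	primary malignant neoplasm of body of stomach
disease type	低分化腺癌	poorly differentiated adenocarcinoma
disease type	中分化腺癌	moderately differentiated adenocarcinoma
disease type	高分化腺癌	well differentiated adenocarcinoma
disease type	印戒细胞癌	signet ring cell carcinoma
disease type	粘液腺癌	mucinous adenocarcinoma
disease type	管状腺癌	tubular adenocarcinoma
symptom	恶心	nausea
symptom	呕吐	vomiting
symptom	返酸	acid regurgitation
symptom	嗳气	belching
symptom	上腹闷痛	epigastric dull pain
symptom	上腹部不适	epigastric discomfort
symptom	腹胀	abdominal distension
symptom	腹泻	diarrhea
symptom	便血	hematochezia
symptom	乏力	fatigue
symptom	食欲下降	decreased appetite
symptom	阵发性加剧	paroxysmal aggravation
sign	压痛	tenderness
sign	反跳痛	rebound tenderness
sign	肠鸣音亢进	hyperactive bowel sounds
sign	移动性浊音	shifting dullness
sign	腹部包块	abdominal mass
body structure	胃体	body of stomach
body structure	胃角	angle of stomach
body structure	胃窦	gastric antrum
body structure	贲门	cardia
body structure	直肠	rectum
body structure	结肠	colon
body structure	十二指肠	duodenum
body structure	食管	esophagus
body structure	肝脏	liver
body structure	胆囊	gallbladder
body structure	上腹部	epigastrium
test	胃镜检查	gastroscopy	胃镜
test	肠镜检查	colonoscopy	肠镜
test	CT检查	computed tomography
test	病理检查	pathological examination
test	超声检查	ultrasonography
test	血常规检查	complete blood count	血常规
test	磁共振检查	magnetic resonance imaging
surgery	胃癌根治术	radical gastrectomy	胃癌根治|根治性胃癌根治术
surgery	Miles手术	Miles operation
surgery	Hartmann手术	Hartmann operation
surgery	Dixon手术	Dixon operation
surgery	毕I式吻合术	Billroth I anastomosis	毕I式吻合
surgery	阑尾切除术	appendectomy
medicine	奥沙利铂	oxaliplatin
medicine	卡培他滨	capecitabine
medicine	氟尿嘧啶	fluorouracil
medicine	替吉奥	tegafur
medicine	亚叶酸钙	calcium leucovorin
medicine	顺铂	cisplatin
histological grade	I级	grade I
histological grade	II级	grade II
histological grade	III级	grade III
pathological stage	pT1N0M0	pT1N0M0
pathological stage	pT2N1M0	pT2N1M0
pathological stage	pT3N2M0	pT3N2M0
pathological stage	pT4N1M1	pT4N1M1
naked eye type	溃疡型	ulcerative type
naked eye type	隆起型	protruding type
naked eye type	浸润型	infiltrative type
tumor size	3*2*1CM	3*2*1CM
tumor size	5*4*2CM	5*4*2CM
tumor size	14*9*1.6CM	14*9*1.6CM
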